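"""Spectra-diet association: distances, permutation tests, ordination.

Diet read counts are first converted to relative read abundances (RRA, rows
summing to one).  Association between the spectral and dietary views of the
same samples is then quantified two ways:

* a **Mantel test** correlating the off-diagonal entries of two distance
  matrices (Bray-Curtis on diet RRA; Euclidean on preprocessed spectra),
  with significance from joint row/column permutations;
* a **Procrustes test** (PROTEST) superimposing low-dimensional ordinations
  of the two distance matrices and permuting rows of one configuration;
  m2 is the residual sum of squares after optimal translation, scaling and
  rotation, and the Procrustes correlation is sqrt(1 - m2).

Ordinations are classical principal coordinates (metric MDS): double-center
the squared distances, eigen-decompose, keep the top axes with positive
eigenvalues, with a deterministic sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import DegenerateInputError, ValidationError


def rra_transform(counts: pd.DataFrame):
    """Read counts (samples x taxa) -> relative read abundances.

    Non-numeric identifier columns (``sample_id``) are carried through.
    Rows with zero total reads are dropped and reported in the returned
    list.  Output rows sum to 1 within 1e-12.
    """
    counts = counts.copy()
    id_col = None
    if "sample_id" in counts.columns:
        id_col = counts.pop("sample_id")
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValidationError("negative read counts")
    totals = mat.sum(axis=1)
    keep = totals > 0
    dropped = []
    if id_col is not None:
        dropped = [str(s) for s in id_col[~keep]]
    elif (~keep).any():
        dropped = [str(i) for i in np.flatnonzero(~keep)]
    rra = mat[keep] / totals[keep][:, None]
    out = pd.DataFrame(rra, columns=counts.columns)
    if id_col is not None:
        out.insert(0, "sample_id", id_col[keep].to_numpy())
    return out, dropped


def _matrix_of(diet) -> np.ndarray:
    if isinstance(diet, pd.DataFrame):
        cols = [c for c in diet.columns if c != "sample_id"]
        return diet[cols].to_numpy(dtype=float)
    return np.asarray(diet, dtype=float)


def bray_curtis(diet) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix: sum|x-y| / sum(x+y)."""
    mat = _matrix_of(diet)
    if np.any(mat < 0):
        raise ValidationError("Bray-Curtis requires non-negative abundances")
    return squareform(pdist(mat, metric="braycurtis"))


def euclidean_distance(X) -> np.ndarray:
    """Euclidean distance matrix (the spectra-side default)."""
    return squareform(pdist(np.asarray(X, dtype=float), metric="euclidean"))


def _check_distance_matrix(D: np.ndarray, name: str) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError(f"{name} is not square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValidationError(f"{name} is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValidationError(f"{name} has a nonzero diagonal")
    return D


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    alternative: str
    null_distribution: np.ndarray

    def summary(self) -> str:
        return (
            f"Mantel test: r = {self.statistic:.4f}, "
            f"p = {self.p_value:.4g} ({self.n_permutations} permutations, "
            f"{self.alternative})"
        )


def mantel_test(
    D1,
    D2,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    alternative: str = "two-sided",
) -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    The statistic is the Pearson correlation of the upper off-diagonal
    triangles; the null permutes the row/column order of ``D2`` jointly;
    p = (#{permuted statistic as extreme} + 1) / (n_perm + 1).
    """
    D1 = _check_distance_matrix(D1, "D1")
    D2 = _check_distance_matrix(D2, "D2")
    if D1.shape != D2.shape:
        raise ValidationError("distance matrices differ in size")
    if alternative not in ("two-sided", "greater"):
        raise ValidationError("alternative must be 'two-sided' or 'greater'")
    n = D1.shape[0]
    iu = np.triu_indices(n, k=1)
    x = D1[iu]
    if x.std() == 0:
        raise DegenerateInputError("D1 has zero variance in its distances")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def corr(d2mat):
        y = d2mat[iu]
        sy = y.std()
        if sy == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(D2)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = corr(D2[np.ix_(perm, perm)])
    if alternative == "greater":
        extreme = np.sum(null >= r_obs)
    else:
        extreme = np.sum(np.abs(null) >= abs(r_obs))
    p = (extreme + 1) / (n_perm + 1)
    return MantelResult(r_obs, float(p), n_perm, alternative, null)


@dataclass
class ProcrustesResult:
    m2: float
    correlation: float
    p_value: float
    n_permutations: int
    null_distribution: np.ndarray

    def summary(self) -> str:
        return (
            f"Procrustes test: m2 = {self.m2:.4f}, correlation = "
            f"{self.correlation:.4f}, p = {self.p_value:.4g} "
            f"({self.n_permutations} permutations)"
        )


def _standardize(X: np.ndarray) -> np.ndarray:
    X = X - X.mean(axis=0)
    ss = np.sqrt((X**2).sum())
    if ss == 0:
        raise DegenerateInputError("configuration has zero spread")
    return X / ss


def _procrustes_corr(X1: np.ndarray, X2: np.ndarray) -> float:
    """Procrustes correlation = sum of singular values of X1' X2 after
    centering and unit-scaling both configurations."""
    s = np.linalg.svd(X1.T @ X2, compute_uv=False)
    return float(s.sum())


def procrustes_test(
    config1,
    config2,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> ProcrustesResult:
    """Symmetric Procrustes superimposition with a permutation null.

    Both configurations (samples x k) are centered and scaled to unit sum
    of squares; the optimal rotation comes from the singular decomposition
    of their cross-product.  m2 = 1 - corr^2 is the residual sum of
    squares; the null permutes rows of ``config2``.
    """
    X1 = _standardize(np.asarray(config1, dtype=float))
    X2 = _standardize(np.asarray(config2, dtype=float))
    if X1.shape[0] != X2.shape[0]:
        raise ValidationError("configurations differ in sample count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    corr = _procrustes_corr(X1, X2)
    m2 = 1.0 - corr**2
    n = X1.shape[0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = _procrustes_corr(X1, _standardize(X2[perm]))
    p = (np.sum(null >= corr) + 1) / (n_perm + 1)
    return ProcrustesResult(float(m2), corr, float(p), n_perm, null)


def ordinate_pcoa(D, k: int = 2) -> np.ndarray:
    """Classical principal-coordinates analysis of a distance matrix.

    Double-centers -0.5 D^2, eigen-decomposes, and returns the first ``k``
    axes scaled by sqrt(eigenvalue).  Requesting more axes than there are
    positive eigenvalues is an error.  Sign convention: on each axis the
    coordinate of largest magnitude is positive.
    """
    D = _check_distance_matrix(D, "D")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    w, U = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    pos = w > max(1e-8 * max(w.max(), 0.0), 1e-12)
    n_pos = int(pos.sum())
    if k > n_pos:
        raise ValidationError(
            f"requested {k} axes but only {n_pos} positive eigenvalues"
        )
    coords = U[:, :k] * np.sqrt(w[:k])
    for j in range(k):
        i = int(np.argmax(np.abs(coords[:, j])))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def diet_spectra_association(
    spectra_matrix,
    diet,
    n_perm: int = 999,
    seed: int = 0,
    k: int = 2,
) -> dict:
    """Run both association tests between aligned spectra and diet tables.

    Spectra-side distance is Euclidean (Bray-Curtis is undefined on
    SNV-normalized spectra, which contain negatives); diet-side is
    Bray-Curtis on RRA.  The Procrustes test operates on k-dimensional
    principal coordinates of each matrix.
    """
    D_spec = euclidean_distance(spectra_matrix)
    D_diet = bray_curtis(diet)
    mantel = mantel_test(D_spec, D_diet, n_perm=n_perm, seed=seed)
    c1 = ordinate_pcoa(D_spec, k=k)
    c2 = ordinate_pcoa(D_diet, k=k)
    procrustes = procrustes_test(c1, c2, n_perm=n_perm, seed=seed + 1)
    return {"mantel": mantel, "procrustes": procrustes,
            "pcoa_spectra": c1, "pcoa_diet": c2}
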