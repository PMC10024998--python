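"""Multivariate adaptive regression splines (MARS), from scratch.

The model is a sum of basis functions, each a product of at most ``degree``
hinge functions max(0, x_v - t) or max(0, t - x_v), never two hinges on the
same variable within one product.  Fitting proceeds in two passes:

* **forward**: greedily add reflected hinge pairs (parent basis x both hinge
  directions) that maximize the squared-error reduction, scored against the
  orthogonalized residual so each candidate costs a few BLAS calls;
* **backward**: delete terms one at a time to minimize the generalized
  cross-validation score GCV = (RSS/n) / (1 - C(m)/n)^2 with effective
  parameter count C(m) = m + penalty * (m - 1) / 2, and return the
  GCV-minimal subset along the deletion trace.

Supports multiresponse Y (needed by optimal-scoring discriminant analysis),
deterministic tie-breaking (lowest variable index, then lowest knot), a
minimum-span rule thinning candidate knots, and a ``fast_k`` cap on the
number of parent terms searched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NumericalError, ValidationError

#: A hinge: (variable index, knot, direction).  direction +1 means
#: max(0, x - knot); -1 means max(0, knot - x).  A basis function is a
#: tuple of hinges; the empty tuple is the intercept.
Hinge = tuple[int, float, int]
BasisFunction = tuple[Hinge, ...]


def evaluate_basis(defs: list[BasisFunction], X: np.ndarray) -> np.ndarray:
    """Design matrix of the basis functions at rows of X."""
    n = X.shape[0]
    cols = np.empty((n, len(defs)))
    for j, bf in enumerate(defs):
        col = np.ones(n)
        for (v, t, d) in bf:
            col = col * np.maximum(0.0, d * (X[:, v] - t))
        cols[:, j] = col
    return cols


def _gcv(rss: float, n: int, m: int, penalty: float) -> float:
    c = m + penalty * (m - 1) / 2.0
    denom = 1.0 - c / n
    if denom <= 0:
        return np.inf
    return (rss / n) / denom**2


@dataclass
class MarsResults:
    """Fitted MARS model: pruned basis, coefficients, and the GCV trace."""

    basis: list[BasisFunction]
    coef: np.ndarray  # (n_terms, n_responses)
    gcv_: float
    rss_: float
    n_obs: int
    n_features: int
    penalty: float
    degree: int
    max_terms: int
    forward_basis: list[BasisFunction] = field(default_factory=list)
    backward_trace: list[dict] = field(default_factory=list)  # per deletion step
    response_names: list[str] | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"predict: X has {X.shape[1]} columns, model expects {self.n_features}"
            )
        if not np.all(np.isfinite(X)):
            raise ValidationError("predict: X contains non-finite values")
        return evaluate_basis(self.basis, X) @ self.coef

    @property
    def selected_variables(self) -> np.ndarray:
        """Sorted indices of variables appearing in the pruned basis."""
        vs = {v for bf in self.basis for (v, _, _) in bf}
        return np.array(sorted(vs), dtype=int)

    def variable_importance(self) -> np.ndarray:
        """Residual-sum-of-squares importance per variable, max scaled to 100.

        Walking the backward deletion trace from the selected model down to
        the intercept, the RSS increase of each deletion is attributed to
        every variable in the deleted term; variables absent from the pruned
        basis score exactly 0.
        """
        scores = np.zeros(self.n_features)
        selected = set(self.basis)
        for step in self.backward_trace:
            bf = step["deleted"]
            if bf not in selected or not bf:
                continue
            for (v, _, _) in bf:
                scores[v] += max(step["rss_increase"], 0.0)
        top = scores.max()
        if top > 0:
            scores = scores / top * 100.0
        return scores

    def summary(self) -> str:
        lines = [
            "MARS regression results",
            "=" * 54,
            f"observations: {self.n_obs}    features: {self.n_features}",
            f"degree: {self.degree}    penalty: {self.penalty}    "
            f"max_terms: {self.max_terms}",
            f"terms (forward): {len(self.forward_basis)}    "
            f"terms (pruned): {len(self.basis)}",
            f"RSS: {self.rss_:.6g}    GCV: {self.gcv_:.6g}",
            "-" * 54,
            f"{'term':40s}{'coef':>12s}",
        ]
        for bf, c in zip(self.basis, self.coef):
            name = " * ".join(
                (f"max(0, x{v} - {t:.4g})" if d > 0 else f"max(0, {t:.4g} - x{v})")
                for (v, t, d) in bf
            ) or "(intercept)"
            cval = c[0] if np.ndim(c) else c
            lines.append(f"{name[:40]:40s}{cval:12.4g}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "basis": [[list(h) for h in bf] for bf in self.basis],
            "coef": np.asarray(self.coef).tolist(),
            "gcv": self.gcv_,
            "rss": self.rss_,
            "n_obs": self.n_obs,
            "n_features": self.n_features,
            "penalty": self.penalty,
            "degree": self.degree,
            "max_terms": self.max_terms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MarsResults":
        basis = [tuple((int(v), float(t), int(s)) for (v, t, s) in bf) for bf in d["basis"]]
        return cls(
            basis=basis,
            coef=np.asarray(d["coef"], dtype=float),
            gcv_=d["gcv"],
            rss_=d["rss"],
            n_obs=d["n_obs"],
            n_features=d["n_features"],
            penalty=d["penalty"],
            degree=d["degree"],
            max_terms=d["max_terms"],
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


class MarsRegression:
    """MARS model builder.

    Parameters
    ----------
    X : (n, p) array
        Predictors; constant columns are tolerated but never selected.
    Y : (n,) or (n, K) array
        One or several responses sharing the basis (RSS summed over columns).
    degree : int
        Maximum number of hinges multiplied in one basis function (1-3).
    max_terms : int, optional
        Cap on basis functions including the intercept.  Default
        ``min(200, max(2 n / 3, 9))``.
    penalty : float, optional
        GCV penalty per pair; default 2 for degree 1, else 3.
    minspan : int
        Keep every ``minspan``-th candidate knot among the sorted observed
        values of a variable (1 = every observed value).
    fast_k : int
        Number of parent terms searched per forward step.
    """

    def __init__(
        self,
        X,
        Y,
        degree: int = 1,
        max_terms: int | None = None,
        penalty: float | None = None,
        minspan: int = 3,
        fast_k: int = 20,
        forward_tol: float = 1e-10,
    ):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2:
            raise ValidationError("X must be 2-D")
        if Y.ndim == 1:
            Y = Y[:, None]
        n = X.shape[0]
        if Y.shape[0] != n:
            raise ValidationError("X and Y row counts differ")
        if n < 8:
            raise ValidationError(f"need at least 8 observations, got {n}")
        if degree not in (1, 2, 3):
            raise ValidationError("degree must be 1, 2 or 3")
        if not np.all(np.isfinite(X)):
            raise ValidationError("X contains missing or non-finite values")
        if not np.all(np.isfinite(Y)):
            raise ValidationError("Y contains missing or non-finite values")
        if max_terms is None:
            max_terms = int(min(200, max(2 * n // 3, 9)))
        if max_terms < 1:
            raise ValidationError("max_terms must be >= 1")
        self.X, self.Y = X, Y
        self.n, self.p = X.shape
        self.degree = degree
        self.max_terms = max_terms
        self.penalty = float(penalty if penalty is not None else (2.0 if degree == 1 else 3.0))
        self.minspan = max(1, int(minspan))
        self.fast_k = max(1, int(fast_k))
        self.forward_tol = forward_tol

    # -- forward pass -------------------------------------------------------
    def _candidate_knots(self, x_active: np.ndarray) -> np.ndarray:
        """Thinned candidate knots: sorted unique values, max excluded."""
        u = np.unique(x_active)
        if u.size < 2:
            return np.empty(0)
        u = u[:-1]  # knot at the maximum gives an all-zero upward hinge
        return u[:: self.minspan]

    def _forward(self):
        X, Y, n = self.X, self.Y, self.n
        defs: list[BasisFunction] = [()]
        B = np.ones((n, 1))
        ymean = Y.mean(axis=0)
        rss0 = float(((Y - ymean) ** 2).sum())
        tiny = 1e-24 * max(1.0, float((Y**2).sum()))
        if rss0 <= tiny:
            return defs, B
        norm_tol = 1e-12

        while len(defs) + 2 <= self.max_terms:
            Q, _ = np.linalg.qr(B)
            Ry = Y - Q @ (Q.T @ Y)
            rss_cur = float((Ry**2).sum())
            if rss_cur <= max(self.forward_tol * rss0, tiny):
                break

            best_score = 0.0
            best = None  # (parent_idx, var, knot)
            parent_order = [i for i, d in enumerate(defs) if len(d) < self.degree]
            for pi in parent_order[: self.fast_k]:
                a = B[:, pi]
                active = a != 0.0
                if active.sum() < 2:
                    continue
                used_vars = {v for (v, _, _) in defs[pi]}
                c1_blocks, c2_blocks, var_ids, knot_vals = [], [], [], []
                for v in range(self.p):
                    if v in used_vars:
                        continue
                    knots = self._candidate_knots(X[active, v])
                    if knots.size == 0:
                        continue
                    xv = X[:, v][:, None]
                    c1_blocks.append(a[:, None] * np.maximum(0.0, xv - knots[None, :]))
                    c2_blocks.append(a[:, None] * np.maximum(0.0, knots[None, :] - xv))
                    var_ids.append(np.full(knots.size, v))
                    knot_vals.append(knots)
                if not c1_blocks:
                    continue
                C1 = np.concatenate(c1_blocks, axis=1)
                C2 = np.concatenate(c2_blocks, axis=1)
                var_ids = np.concatenate(var_ids)
                knot_vals = np.concatenate(knot_vals)

                U1 = C1 - Q @ (Q.T @ C1)
                U2 = C2 - Q @ (Q.T @ C2)
                n1 = np.einsum("ij,ij->j", U1, U1)
                n2 = np.einsum("ij,ij->j", U2, U2)
                c12 = np.einsum("ij,ij->j", U1, U2)
                P1 = U1.T @ Ry  # (N, K)
                P2 = U2.T @ Ry
                s1 = (C1**2).sum(axis=0)
                s2 = (C2**2).sum(axis=0)
                ok1 = n1 > norm_tol * np.maximum(s1, 1e-30)
                with np.errstate(divide="ignore", invalid="ignore"):
                    score1 = np.where(ok1, (P1**2).sum(axis=1) / np.where(ok1, n1, 1.0), 0.0)
                    ratio = np.where(ok1, c12 / np.where(ok1, n1, 1.0), 0.0)
                    v2sq = n2 - ratio * c12
                    proj2 = P2 - ratio[:, None] * P1
                    ok2 = v2sq > norm_tol * np.maximum(s2, 1e-30)
                    score2 = np.where(
                        ok2, (proj2**2).sum(axis=1) / np.where(ok2, v2sq, 1.0), 0.0
                    )
                score = score1 + score2
                j = int(np.argmax(score))
                if score[j] > best_score * (1 + 1e-12) and score[j] > 0:
                    best_score = float(score[j])
                    best = (pi, int(var_ids[j]), float(knot_vals[j]))

            if best is None or best_score <= self.forward_tol * rss0:
                break
            pi, v, t = best
            parent_def = defs[pi]
            a = B[:, pi]
            added = False
            for direction in (+1, -1):
                col = a * np.maximum(0.0, direction * (X[:, v] - t))
                Qc = Q.T @ col
                resid = col - Q @ Qc
                if (resid**2).sum() > norm_tol * max((col**2).sum(), 1e-30):
                    defs.append(parent_def + ((v, t, direction),))
                    B = np.column_stack([B, col])
                    Q, _ = np.linalg.qr(B)
                    added = True
            if not added:
                break
        return defs, B

    # -- backward pass ------------------------------------------------------
    def _backward(self, defs: list[BasisFunction], B: np.ndarray):
        n, Y = self.n, self.Y

        def rss_of(cols: list[int]) -> float:
            coef, res, rank, _ = np.linalg.lstsq(B[:, cols], Y, rcond=None)
            fitted = B[:, cols] @ coef
            return float(((Y - fitted) ** 2).sum())

        current = list(range(len(defs)))
        rss_full = rss_of(current)
        best_gcv = _gcv(rss_full, n, len(current), self.penalty)
        best_subset = list(current)
        trace = []
        prev_rss = rss_full
        while len(current) > 1:
            cand_best = None
            for t_idx in current:
                if not defs[t_idx]:  # never delete the intercept
                    continue
                cols = [c for c in current if c != t_idx]
                r = rss_of(cols)
                g = _gcv(r, n, len(cols), self.penalty)
                if cand_best is None or g < cand_best[0] - 1e-15 * max(abs(g), 1.0):
                    cand_best = (g, t_idx, r)
            if cand_best is None:
                break
            g, t_idx, r = cand_best
            current = [c for c in current if c != t_idx]
            trace.append(
                {
                    "deleted": defs[t_idx],
                    "gcv": g,
                    "rss": r,
                    "rss_increase": r - prev_rss,
                    "n_terms": len(current),
                }
            )
            prev_rss = r
            if g <= best_gcv:
                best_gcv = g
                best_subset = list(current)
        return best_subset, best_gcv, trace

    def fit(self) -> MarsResults:
        defs, B = self._forward()
        best_subset, best_gcv, trace = self._backward(defs, B)
        sel_defs = [defs[i] for i in best_subset]
        Bsel = B[:, best_subset]
        coef, _, rank, _ = np.linalg.lstsq(Bsel, self.Y, rcond=None)
        if not np.all(np.isfinite(coef)):
            raise NumericalError("non-finite coefficients in final least squares")
        rss = float(((self.Y - Bsel @ coef) ** 2).sum())
        return MarsResults(
            basis=sel_defs,
            coef=coef,
            gcv_=best_gcv,
            rss_=rss,
            n_obs=self.n,
            n_features=self.p,
            penalty=self.penalty,
            degree=self.degree,
            max_terms=self.max_terms,
            forward_basis=defs,
            backward_trace=trace,
        )
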