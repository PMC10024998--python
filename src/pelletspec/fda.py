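"""Flexible discriminant analysis (FDA) via optimal scoring on a MARS basis.

Linear discriminant analysis can be recast as a regression problem: regress
a class-indicator matrix on the predictors, then find the "optimal scores"
for the classes that the regression predicts best.  Replacing the linear
regression with any flexible multiresponse regressor generalizes LDA to
nonlinear decision boundaries; here the regressor is the package's MARS
engine, so the discriminant subspace is spanned by hinge-function features
of the spectra.

Fitting:

1. build the n x K class-indicator matrix G and regress it on X with a
   single multiresponse MARS model, giving fitted values Yhat = P G for a
   projection P;
2. eigen-decompose A = Pi^{-1/2} (G' Yhat / n) Pi^{-1/2} (Pi = diagonal
   class proportions), discarding the trivial unit eigenvalue, to obtain up
   to K-1 canonical directions ordered by decreasing discrimination
   (eigenvalues lambda_l in (0, 1));
3. map samples to canonical coordinates z_l(x) = eta(x)' theta_l scaled by
   1 / sqrt(lambda_l (1 - lambda_l)), so plain Euclidean nearest-centroid
   distance in z-space is the FDA classification rule.

Sign indeterminacy is fixed by making the first nonzero entry of each
score vector positive.  Ties in centroid distance break to the first class
in the model's class list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import NumericalError, ValidationError
from .mars import MarsRegression, MarsResults

_EIG_TOL = 1e-9
_LAMBDA_CLIP = 1e-8


@dataclass
class FDAResults:
    """Fitted flexible discriminant model."""

    classes: list[str]
    mars_: MarsResults
    scores: np.ndarray        # (K, q) optimal score vectors theta_l
    eigenvalues: np.ndarray   # (q,) discrimination eigenvalues in (0, 1)
    dim_scale: np.ndarray     # (q,) 1/sqrt(lambda (1 - lambda))
    centroids: np.ndarray     # (K, q) class centroids in canonical space
    class_counts: np.ndarray  # (K,)
    training_accuracy: float = float("nan")
    canonical_train: np.ndarray | None = None
    canonical_range: np.ndarray | None = None  # (2, q): per-axis train min/max

    @property
    def canonical_dim(self) -> int:
        return self.scores.shape[1]

    def canonical_coordinates(self, X) -> np.ndarray:
        """Map samples to the canonical discriminant space (n x q)."""
        eta = self.mars_.predict(X)
        return (eta @ self.scores) * self.dim_scale

    def predict(self, X):
        """Classify by nearest centroid in canonical space.

        Returns ``(labels, canonical coordinates, squared centroid
        distances)``; distance ties resolve to the first class in
        ``self.classes``.
        """
        z = self.canonical_coordinates(X)
        d2 = ((z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)  # argmin takes the first index on ties
        labels = np.asarray(self.classes, dtype=object)[idx]
        return labels, z, d2

    def variable_importance(self) -> np.ndarray:
        return self.mars_.variable_importance()

    def extrapolation_flags(self, X) -> np.ndarray:
        """True where a sample's canonical coordinates fall outside the
        per-axis range of the training data (misclassification-risk triage)."""
        if self.canonical_range is None:
            raise ValidationError("model carries no training canonical range")
        z = self.canonical_coordinates(X)
        lo, hi = self.canonical_range
        return np.any((z < lo) | (z > hi), axis=1)

    def summary(self) -> str:
        lines = [
            "Flexible discriminant analysis (MARS basis)",
            "=" * 54,
            f"classes: {', '.join(self.classes)}",
            f"canonical dimension: {self.canonical_dim}",
            f"basis terms: {len(self.mars_.basis)}    "
            f"selected wavelengths: {self.mars_.selected_variables.size}",
            f"training accuracy: {self.training_accuracy:.3f}",
            "-" * 54,
            f"{'axis':>4s}{'eigenvalue':>14s}{'scale':>12s}",
        ]
        for l, (lam, sc) in enumerate(zip(self.eigenvalues, self.dim_scale), 1):
            lines.append(f"{l:4d}{lam:14.4f}{sc:12.4g}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "mars": self.mars_.to_dict(),
            "scores": self.scores.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "dim_scale": self.dim_scale.tolist(),
            "centroids": self.centroids.tolist(),
            "class_counts": self.class_counts.tolist(),
            "training_accuracy": self.training_accuracy,
            "canonical_range": None
            if self.canonical_range is None
            else self.canonical_range.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FDAResults":
        return cls(
            classes=list(d["classes"]),
            mars_=MarsResults.from_dict(d["mars"]),
            scores=np.asarray(d["scores"], dtype=float),
            eigenvalues=np.asarray(d["eigenvalues"], dtype=float),
            dim_scale=np.asarray(d["dim_scale"], dtype=float),
            centroids=np.asarray(d["centroids"], dtype=float),
            class_counts=np.asarray(d["class_counts"], dtype=int),
            training_accuracy=float(d.get("training_accuracy", float("nan"))),
            canonical_range=None
            if d.get("canonical_range") is None
            else np.asarray(d["canonical_range"], dtype=float),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "FDAResults":
        return cls.from_dict(json.loads(s))


class FlexibleDiscriminantAnalysis:
    """FDA model builder on a shared multiresponse MARS basis.

    Parameters mirror :class:`~pelletspec.mars.MarsRegression`; ``classes``
    fixes the class order (default: sorted unique labels), which is also
    the deterministic tie-break order at prediction time.
    """

    def __init__(
        self,
        X,
        labels,
        degree: int = 2,
        max_terms: int | None = None,
        penalty: float | None = None,
        classes: list[str] | None = None,
        **mars_kwargs,
    ):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        if X.shape[0] != labels.shape[0]:
            raise ValidationError("X and labels row counts differ")
        found = [str(c) for c in np.unique(labels)]
        if classes is None:
            classes = found
        else:
            classes = [str(c) for c in classes]
            extra = set(found) - set(classes)
            if extra:
                raise ValidationError(f"labels outside class list: {sorted(extra)}")
        if len(found) < 2:
            raise ValidationError("need at least 2 classes present in labels")
        counts = np.array([(labels == c).sum() for c in classes])
        thin = [c for c, n in zip(classes, counts) if 0 < n < 2]
        if thin:
            raise ValidationError(f"classes with fewer than 2 samples: {thin}")
        self.X = X
        self.labels = labels.astype(str)
        self.classes = classes
        self.class_counts = counts
        self.degree = degree
        self.max_terms = max_terms
        self.penalty = penalty
        self.mars_kwargs = mars_kwargs

    def fit(self) -> FDAResults:
        X, labels, classes = self.X, self.labels, self.classes
        n, K = X.shape[0], len(classes)
        G = np.zeros((n, K))
        for k, c in enumerate(classes):
            G[labels == c, k] = 1.0

        mars = MarsRegression(
            X,
            G,
            degree=self.degree,
            max_terms=self.max_terms,
            penalty=self.penalty,
            **self.mars_kwargs,
        ).fit()
        from .mars import evaluate_basis

        B = evaluate_basis(mars.basis, X)
        Yhat = B @ mars.coef

        pi = G.sum(axis=0) / n
        present = pi > 0
        if not np.all(present):
            # classes listed but absent from training: centroids undefined
            raise ValidationError(
                f"classes absent from training data: "
                f"{[c for c, p in zip(classes, present) if not p]}"
            )
        inv_sqrt_pi = 1.0 / np.sqrt(pi)
        M = G.T @ Yhat / n
        A = inv_sqrt_pi[:, None] * M * inv_sqrt_pi[None, :]
        A = (A + A.T) / 2.0
        u0 = np.sqrt(pi)
        A = A - np.outer(u0, u0)  # deflate the trivial unit eigenvalue

        w, U = np.linalg.eigh(A)
        order = np.argsort(w)[::-1]
        w, U = w[order], U[:, order]
        keep = w > _EIG_TOL
        q = int(min(K - 1, keep.sum()))
        if q == 0:
            # no discriminative signal (e.g. intercept-only regression):
            # keep one axis; coordinates collapse, centroids coincide and
            # prediction falls back to the deterministic tie rule.
            q = 1
        w = np.clip(w[:q], _LAMBDA_CLIP, 1.0 - _LAMBDA_CLIP)
        theta = U[:, :q] * inv_sqrt_pi[:, None]

        # deterministic sign: first nonzero entry of each score vector > 0
        for l in range(q):
            col = theta[:, l]
            nz = np.flatnonzero(np.abs(col) > 1e-12)
            if nz.size and col[nz[0]] < 0:
                theta[:, l] = -col

        dim_scale = 1.0 / np.sqrt(w * (1.0 - w))
        z = (Yhat @ theta) * dim_scale
        centroids = np.vstack([z[labels == c].mean(axis=0) for c in classes])

        result = FDAResults(
            classes=classes,
            mars_=mars,
            scores=theta,
            eigenvalues=w,
            dim_scale=dim_scale,
            centroids=centroids,
            class_counts=self.class_counts,
            canonical_train=z,
            canonical_range=np.vstack([z.min(axis=0), z.max(axis=0)]),
        )
        pred, _, _ = result.predict(X)
        result.training_accuracy = float((pred == labels).mean())
        return result


def predict_direct_mars(mars: MarsResults, X, classes: list[str]):
    """Classify with a direct (non-FDA) MARS fit on class indicators.

    The predicted label is the class whose indicator score is largest;
    ties break to the first class in ``classes``.
    """
    scores = mars.predict(X)
    if scores.shape[1] != len(classes):
        raise ValidationError("score columns do not match class list")
    idx = np.argmax(scores, axis=1)
    return np.asarray(classes, dtype=object)[idx], scores
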