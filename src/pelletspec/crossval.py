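"""Repeated double Monte Carlo cross-validation (rdMCCV).

The calibration models are validated by repeatedly splitting the data into
a calibration set and a test set, refitting the full model — including
variable selection — inside every split, and aggregating:

* per-iteration misclassification rates and per-class prediction
  accuracies (recall),
* per-sample outcome records (0 = misclassified, 1 = correct) whenever a
  sample lands in a test set, which average to the individual sample
  prediction accuracy (IPA),
* per-wavelength counts of iterations in which the wavelength had
  variable importance > 0.

The default scheme repeats 200 iterations at each of three test fractions
(5%, 10%, 20%), i.e. 600 model fits, with splits stratified so each
stratum (e.g. species x exposure week) contributes its fixed share to the
test set.  Per-iteration seeds derive from the master seed by a
counter-based rule, so any single iteration can be reproduced in
isolation and results are invariant to execution order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import StratificationError, ValidationError
from .fda import FDAResults, FlexibleDiscriminantAnalysis, predict_direct_mars
from .mars import MarsRegression
from .spectra import SpectralDataset

logger = logging.getLogger(__name__)


@dataclass
class ModelSpec:
    """What to fit inside each rdMCCV iteration."""

    response: str = "species"          # 'species' or 'genus'
    classifier: str = "fda_mars"       # 'fda_mars' or 'mars_direct'
    degree: int = 2
    max_terms: int | None = None
    penalty: float | None = None
    minspan: int = 3
    fast_k: int = 20

    def validate(self) -> None:
        if self.response not in ("species", "genus"):
            raise ValidationError(f"unknown response {self.response!r}")
        if self.classifier not in ("fda_mars", "mars_direct"):
            raise ValidationError(f"unknown classifier {self.classifier!r}")


@dataclass
class SplitScheme:
    """Resampling design: test fractions, repeats, stratification, seed."""

    fractions: tuple[float, ...] = (0.05, 0.10, 0.20)
    iterations_per_fraction: int = 200
    stratify_by: tuple[str, ...] = ("species",)
    rng_seed: int = 0
    strict: bool = False  # raise (instead of warn) on strata smaller than 2

    def validate(self) -> None:
        if not self.fractions or any(not 0 < f < 1 for f in self.fractions):
            raise ValidationError("fractions must lie strictly in (0, 1)")
        if self.iterations_per_fraction < 1:
            raise ValidationError("iterations_per_fraction must be >= 1")

    @property
    def total_models(self) -> int:
        return self.iterations_per_fraction * len(self.fractions)

    def iteration_rng(self, fraction_index: int, replicate: int) -> np.random.Generator:
        """Independent stream for one named iteration (counter-based)."""
        return np.random.default_rng(
            np.random.SeedSequence([int(self.rng_seed), fraction_index, replicate])
        )


def _stratum_labels(metadata: pd.DataFrame, keys: tuple[str, ...]) -> pd.Series:
    parts = []
    for k in keys:
        if k not in metadata.columns:
            raise ValidationError(f"stratification key {k!r} missing from metadata")
        col = metadata[k]
        if k == "exposure_week":
            col = col.map(lambda v: "intestinal" if pd.isna(v) else str(int(v)))
        parts.append(col.astype(str))
    if not parts:
        return pd.Series(["all"] * len(metadata), index=metadata.index)
    out = parts[0]
    for p in parts[1:]:
        out = out + "|" + p
    return out


def stratified_split(
    metadata: pd.DataFrame,
    fraction: float,
    keys: tuple[str, ...],
    rng: np.random.Generator,
    strict: bool = False,
):
    """Partition sample_ids into (calibration, test) by stratified draw.

    From each stratum, round-half-up(fraction x size) samples, at least 1
    and at most size - 1, go to the test set.  Strata with fewer than 2
    samples go entirely into calibration (warning), or raise when
    ``strict``.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must lie strictly in (0, 1)")
    strata = _stratum_labels(metadata, keys)
    ids = metadata["sample_id"].astype(str)
    test: list[str] = []
    cal: list[str] = []
    for label in sorted(strata.unique()):
        members = sorted(ids[strata == label])
        size = len(members)
        if size < 2:
            msg = f"stratum {label!r} has {size} sample(s); kept in calibration"
            if strict:
                raise StratificationError(msg)
            logger.warning(msg)
            cal.extend(members)
            continue
        n_test = int(np.floor(fraction * size + 0.5))
        n_test = min(max(n_test, 1), size - 1)
        chosen = rng.choice(size, size=n_test, replace=False)
        chosen_set = {members[i] for i in chosen}
        test.extend(sorted(chosen_set))
        cal.extend(m for m in members if m not in chosen_set)
    return cal, test


@dataclass
class RdMccvResult:
    """Aggregated output of a repeated Monte Carlo cross-validation run."""

    iterations: pd.DataFrame        # fraction, replicate, mcr, n_test, ...
    records: pd.DataFrame           # sample_id, fraction, replicate, true, predicted, correct
    class_accuracy: pd.DataFrame    # fraction, replicate, class, accuracy, n_test
    vi_counts: np.ndarray           # per-wavelength count of iterations with VI > 0
    wavelengths: np.ndarray
    classes: list[str]
    scheme: SplitScheme
    spec: ModelSpec
    skipped: list[dict] = field(default_factory=list)

    @property
    def n_models(self) -> int:
        return len(self.iterations)

    def ipa(self) -> pd.DataFrame:
        return compute_ipa(self.records)

    def summary(self) -> dict:
        """Mean +/- sd misclassification and per-class accuracy, by fraction and pooled."""
        out: dict = {"by_fraction": {}, "pooled": {}}
        for frac, grp in self.iterations.groupby("fraction"):
            out["by_fraction"][f"{frac:g}"] = {
                "mcr_mean": float(grp["mcr"].mean()),
                "mcr_sd": float(grp["mcr"].std(ddof=1)),
                "n_iterations": int(len(grp)),
            }
        out["pooled"] = {
            "mcr_mean": float(self.iterations["mcr"].mean()),
            "mcr_sd": float(self.iterations["mcr"].std(ddof=1)),
            "n_iterations": int(len(self.iterations)),
            "n_skipped": len(self.skipped),
        }
        acc = {}
        for cls, grp in self.class_accuracy.dropna(subset=["accuracy"]).groupby("class"):
            acc[cls] = {
                "accuracy_mean": float(grp["accuracy"].mean()),
                "accuracy_sd": float(grp["accuracy"].std(ddof=1)),
            }
        out["class_accuracy"] = acc
        return out

    def summary_text(self) -> str:
        s = self.summary()
        lines = [
            "Repeated double Monte Carlo cross-validation",
            "=" * 54,
            f"response: {self.spec.response}    classifier: {self.spec.classifier}"
            f"    degree: {self.spec.degree}",
            f"models fitted: {self.n_models}    skipped: {len(self.skipped)}",
            "-" * 54,
        ]
        for frac, d in s["by_fraction"].items():
            lines.append(
                f"fraction {frac:>5s}: misclassification "
                f"{d['mcr_mean']:.3f} +/- {d['mcr_sd']:.3f}  (n={d['n_iterations']})"
            )
        lines.append(
            f"pooled        : misclassification "
            f"{s['pooled']['mcr_mean']:.3f} +/- {s['pooled']['mcr_sd']:.3f}"
        )
        lines.append("-" * 54)
        for cls, d in s["class_accuracy"].items():
            lines.append(
                f"{cls:>10s}: accuracy {100 * d['accuracy_mean']:.1f}% "
                f"+/- {100 * d['accuracy_sd']:.1f}%"
            )
        return "\n".join(lines)

    def to_csvs(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        self.iterations.to_csv(outdir / "iterations.csv", index=False)
        self.records.to_csv(outdir / "outcomes.csv", index=False)
        self.ipa().to_csv(outdir / "ipa.csv", index=False)
        vi = pd.DataFrame(
            {"wavelength": self.wavelengths, "vi_positive_count": self.vi_counts}
        )
        vi.to_csv(outdir / "vi_frequency.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(self.summary(), indent=2), encoding="utf-8"
        )
        for name in ("iterations", "outcomes", "ipa", "vi_frequency", "summary"):
            suffix = "json" if name == "summary" else "csv"
            paths[name] = str(outdir / f"{name}.{suffix}")
        return paths


def _fit_and_predict(spec: ModelSpec, X_cal, y_cal, X_test, classes):
    """One inner model fit + test-set prediction + VI vector."""
    if spec.classifier == "fda_mars":
        fit = FlexibleDiscriminantAnalysis(
            X_cal,
            y_cal,
            degree=spec.degree,
            max_terms=spec.max_terms,
            penalty=spec.penalty,
            classes=classes,
            minspan=spec.minspan,
            fast_k=spec.fast_k,
        ).fit()
        pred, _, _ = fit.predict(X_test)
        return pred, fit.variable_importance()
    # direct multiresponse MARS on class indicators
    K = len(classes)
    G = np.zeros((X_cal.shape[0], K))
    for k, c in enumerate(classes):
        G[np.asarray(y_cal) == c, k] = 1.0
    mars = MarsRegression(
        X_cal,
        G,
        degree=spec.degree,
        max_terms=spec.max_terms,
        penalty=spec.penalty,
        minspan=spec.minspan,
        fast_k=spec.fast_k,
    ).fit()
    pred, _ = predict_direct_mars(mars, X_test, classes)
    return pred, mars.variable_importance()


def run_rdmccv(
    dataset: SpectralDataset,
    spec: ModelSpec,
    scheme: SplitScheme,
) -> RdMccvResult:
    """Run the full rdMCCV design on a preprocessed dataset.

    Each of ``scheme.total_models`` iterations draws its own stratified
    split, refits the classifier on the calibration set only (variable
    selection inside the loop), predicts the test set, and records the
    outcomes.  Iterations whose calibration set lacks one of the classes
    present in the dataset are flagged and skipped, never silently dropped.
    """
    spec.validate()
    scheme.validate()
    labels_all = dataset.labels(spec.response).astype(str)
    classes = sorted(np.unique(labels_all))
    meta = dataset.metadata.reset_index(drop=True)
    id_to_pos = {str(s): i for i, s in enumerate(meta["sample_id"].astype(str))}
    X = dataset.reflectance

    iter_rows, rec_rows, acc_rows, skipped = [], [], [], []
    vi_counts = np.zeros(dataset.wavelengths.size, dtype=int)

    for fi, fraction in enumerate(scheme.fractions):
        for rep in range(scheme.iterations_per_fraction):
            rng = scheme.iteration_rng(fi, rep)
            cal_ids, test_ids = stratified_split(
                meta, fraction, scheme.stratify_by, rng, strict=scheme.strict
            )
            cal_idx = np.array([id_to_pos[s] for s in cal_ids])
            test_idx = np.array([id_to_pos[s] for s in test_ids])
            y_cal, y_test = labels_all[cal_idx], labels_all[test_idx]
            # a class absent (or singleton, unusable for fitting) in the
            # calibration set invalidates the iteration
            missing = sorted(c for c in classes if (y_cal == c).sum() < 2)
            if missing:
                skipped.append(
                    {"fraction": fraction, "replicate": rep, "missing_classes": missing}
                )
                logger.warning(
                    "iteration (%g, %d) skipped: calibration lacks %s",
                    fraction, rep, missing,
                )
                continue
            pred, vi = _fit_and_predict(spec, X[cal_idx], y_cal, X[test_idx], classes)
            correct = (pred == y_test).astype(int)
            mcr = 1.0 - correct.mean()
            iter_rows.append(
                {
                    "fraction": fraction,
                    "replicate": rep,
                    "mcr": mcr,
                    "n_test": len(test_idx),
                    "n_cal": len(cal_idx),
                    "n_selected_wavelengths": int((vi > 0).sum()),
                }
            )
            vi_counts += (vi > 0).astype(int)
            for sid, t, p, c in zip(test_ids, y_test, pred, correct):
                rec_rows.append(
                    {
                        "sample_id": sid,
                        "fraction": fraction,
                        "replicate": rep,
                        "true": t,
                        "predicted": p,
                        "correct": int(c),
                    }
                )
            for cls in classes:
                mask = y_test == cls
                acc_rows.append(
                    {
                        "fraction": fraction,
                        "replicate": rep,
                        "class": cls,
                        "n_test": int(mask.sum()),
                        "accuracy": float(correct[mask].mean()) if mask.any() else np.nan,
                    }
                )

    return RdMccvResult(
        iterations=pd.DataFrame(iter_rows),
        records=pd.DataFrame(rec_rows),
        class_accuracy=pd.DataFrame(acc_rows),
        vi_counts=vi_counts,
        wavelengths=dataset.wavelengths,
        classes=classes,
        scheme=scheme,
        spec=spec,
        skipped=skipped,
    )


class MonteCarloCV:
    """Object-style wrapper: ``MonteCarloCV(dataset, spec, scheme).run()``."""

    def __init__(self, dataset: SpectralDataset, spec: ModelSpec, scheme: SplitScheme):
        self.dataset, self.spec, self.scheme = dataset, spec, scheme

    def run(self) -> RdMccvResult:
        return run_rdmccv(self.dataset, self.spec, self.scheme)


def compute_ipa(records: pd.DataFrame) -> pd.DataFrame:
    """Individual sample prediction accuracy from outcome records.

    IPA(sample) = mean of its correct/incorrect indicators over every
    iteration in which the sample was held out.  The appearance count is
    reported alongside.
    """
    if records.empty:
        return pd.DataFrame(columns=["sample_id", "n_tested", "ipa"])
    grp = records.groupby("sample_id")["correct"]
    out = pd.DataFrame(
        {"sample_id": grp.mean().index, "n_tested": grp.size().to_numpy(),
         "ipa": grp.mean().to_numpy()}
    )
    return out.reset_index(drop=True)


def aggregate_importance(vi_matrix: np.ndarray) -> np.ndarray:
    """Count, per wavelength, the iterations with variable importance > 0.

    ``vi_matrix`` is iterations x wavelengths (scores or booleans).
    """
    vi_matrix = np.asarray(vi_matrix)
    return (vi_matrix > 0).sum(axis=0).astype(int)


def transfer_predict(
    dataset: SpectralDataset,
    train_region: str,
    spec: ModelSpec,
) -> dict:
    """Calibrate on one region, predict every sample of each region.

    Returns per-region misclassification rates and per-class accuracies,
    the training region's figures being resubstitution accuracy.
    """
    spec.validate()
    meta = dataset.metadata
    regions = sorted(meta["region"].astype(str).unique())
    if train_region not in regions:
        raise ValidationError(f"train_region {train_region!r} not in data ({regions})")
    labels_all = dataset.labels(spec.response).astype(str)
    train_mask = (meta["region"].astype(str) == train_region).to_numpy()
    classes = sorted(np.unique(labels_all[train_mask]))
    pred_all, _ = _fit_and_predict_all(
        spec, dataset.reflectance[train_mask], labels_all[train_mask],
        dataset.reflectance, classes,
    )
    out: dict = {"train_region": train_region, "per_region": {}}
    for rg in regions:
        mask = (meta["region"].astype(str) == rg).to_numpy()
        known = mask & np.isin(labels_all, classes)
        correct = (pred_all[known] == labels_all[known]).astype(float)
        per_class = {}
        for cls in classes:
            cmask = known & (labels_all == cls)
            if cmask.any():
                per_class[cls] = float((pred_all[cmask] == cls).mean())
        out["per_region"][rg] = {
            "mcr": float(1.0 - correct.mean()) if known.any() else np.nan,
            "n": int(known.sum()),
            "class_accuracy": per_class,
            "role": "calibration" if rg == train_region else "external",
        }
    return out


def _fit_and_predict_all(spec, X_cal, y_cal, X_eval, classes):
    pred, vi = _fit_and_predict(spec, X_cal, y_cal, X_eval, classes)
    return np.asarray(pred), vi
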