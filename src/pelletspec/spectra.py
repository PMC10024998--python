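"""Reading, validation and preprocessing of fecal NIR reflectance spectra.

A raw scan is a single reflectance measurement of one dried pellet on the
instrument's native wavelength grid (1.4 nm sampling below 1050 nm, 2 nm
above).  The analysis-ready object is a :class:`SpectralDataset`: one
preprocessed spectrum per sample, aligned with a sample-metadata table.

The preprocessing pipeline runs in a fixed order:

    average replicates -> resample to 1 nm -> splice correction
    -> normalization (SNV by default) -> trim to 400-2450 nm

and every step is recorded in a provenance dictionary so a processed
dataset can state exactly how it was produced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    DegenerateInputError,
    RangeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Species vocabulary (field codes) and the genus each belongs to.
SPECIES = ("Llem", "Mruf", "Mrut", "Moec", "Magr")
GENUS_OF = {
    "Llem": "Lemmus",
    "Mruf": "Myodes",
    "Mrut": "Myodes",
    "Moec": "Microtus",
    "Magr": "Microtus",
}
REGIONS = ("WF", "EF")

#: Retained spectral window after trimming (inclusive, nm).
TRIM_LO = 400
TRIM_HI = 2450
#: Full instrument window (inclusive, nm).
FULL_LO = 350
FULL_HI = 2500
#: Default detector-junction wavelengths for splice correction (nm).
DEFAULT_SPLICES = (1000, 1830)
#: Reflectance above this is rejected as physically implausible.
MAX_REFLECTANCE = 1.5


@dataclass
class RawScan:
    """One reflectance scan of one sample on the instrument grid."""

    sample_id: str
    scan_index: int
    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValidationError(
                f"scan {self.sample_id}/{self.scan_index}: wavelength and "
                f"reflectance arrays differ in length"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValidationError(
                f"scan {self.sample_id}/{self.scan_index}: wavelengths not "
                f"strictly increasing"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValidationError(
                f"scan {self.sample_id}/{self.scan_index}: non-finite reflectance"
            )
        if np.any(self.reflectance > MAX_REFLECTANCE) or np.any(self.reflectance < 0):
            raise ValidationError(
                f"scan {self.sample_id}/{self.scan_index}: reflectance outside "
                f"[0, {MAX_REFLECTANCE}]"
            )


@dataclass
class Spectrum:
    """A per-sample spectrum (possibly mid-pipeline)."""

    sample_id: str
    wavelengths: np.ndarray
    reflectance: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)


@dataclass
class SpectralDataset:
    """Aligned reflectance matrix + sample metadata.

    ``reflectance`` is ``n_samples x n_wavelengths``; ``metadata`` has one
    row per sample in the same order, indexed 0..n-1 with a ``sample_id``
    column.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    metadata: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.shape[0] != len(self.metadata):
            raise ValidationError(
                "reflectance row count does not match metadata row count"
            )
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise ValidationError("reflectance column count != wavelength count")
        if self.metadata["sample_id"].duplicated().any():
            dups = self.metadata["sample_id"][self.metadata["sample_id"].duplicated()]
            raise ValidationError(f"duplicate sample_id(s): {sorted(set(dups))[:5]}")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    def subset(self, mask) -> "SpectralDataset":
        """Row subset by boolean mask or integer positions, metadata kept aligned."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SpectralDataset(
            reflectance=self.reflectance[idx],
            wavelengths=self.wavelengths,
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
            provenance=dict(self.provenance),
        )

    def labels(self, response: str) -> np.ndarray:
        """Return per-sample labels for ``response`` in {'species', 'genus'}."""
        if response == "species":
            return self.metadata["species"].to_numpy()
        if response == "genus":
            return self.metadata["species"].map(GENUS_OF).to_numpy()
        raise ValidationError(f"unknown response {response!r}")


# ---------------------------------------------------------------------------
# Preprocessing operations
# ---------------------------------------------------------------------------

def average_replicates(scans: list[RawScan]) -> Spectrum:
    """Pointwise mean of the replicate scans of one sample.

    Pellets are scanned (nominally three times, rotating the holder) and
    the mean spectrum is carried forward.  Fewer or more replicates are
    tolerated with a logged warning.
    """
    if not scans:
        raise ValidationError("average_replicates: no scans supplied")
    sid = scans[0].sample_id
    grid = scans[0].wavelengths
    for s in scans[1:]:
        if s.sample_id != sid:
            raise AlignmentError(
                f"average_replicates: mixed sample_ids {sid!r} and {s.sample_id!r}"
            )
        if s.wavelengths.shape != grid.shape or not np.array_equal(s.wavelengths, grid):
            raise AlignmentError(
                f"average_replicates: mismatched wavelength grids for sample {sid!r}"
            )
    if len(scans) != 3:
        logger.warning("sample %s has %d scans (expected 3)", sid, len(scans))
    mean = np.mean([s.reflectance for s in scans], axis=0)
    return Spectrum(sid, grid.copy(), mean, provenance={"n_scans": len(scans)})


def resample_to_1nm(scan: RawScan | Spectrum, lo: int = FULL_LO, hi: int = FULL_HI) -> Spectrum:
    """Linear interpolation onto the integer-nm grid ``lo..hi``.

    The instrument samples at 1.4 nm below 1050 nm and 2 nm above; the
    analysis grid is 1 nm throughout.  Endpoints present in the input are
    preserved exactly.
    """
    wl, refl = scan.wavelengths, scan.reflectance
    if wl[0] > lo or wl[-1] < hi:
        raise RangeError(
            f"resample: input grid [{wl[0]}, {wl[-1]}] does not span "
            f"requested [{lo}, {hi}]"
        )
    target = np.arange(lo, hi + 1, dtype=float)
    out = np.interp(target, wl, refl)
    prov = dict(getattr(scan, "provenance", {}) or {})
    prov["resampled"] = {"lo": lo, "hi": hi, "step": 1}
    return Spectrum(scan.sample_id, target, out, provenance=prov)


def splice_correction(
    spectrum: Spectrum,
    splice_at: tuple[int, ...] = DEFAULT_SPLICES,
    interval: float = 10.0,
) -> Spectrum:
    """Remove reflectance offsets at detector junctions.

    The instrument class switches detectors at ~1000 and ~1830 nm, which can
    leave step discontinuities.  For each junction, a low-order polynomial
    (quadratic when enough points, else linear) is fitted to the ``interval``
    nm of spectrum just below the junction, extrapolated to the first
    wavelength above it, and the entire post-junction segment is offset so
    its start matches the extrapolation.  Junctions are processed left to
    right.
    """
    wl = spectrum.wavelengths
    refl = spectrum.reflectance.copy()
    for j in sorted(splice_at):
        if j <= wl[0] or j >= wl[-1]:
            raise RangeError(f"splice junction {j} nm at or beyond grid edge")
        pre = (wl <= j) & (wl > j - interval)
        post = wl > j
        if pre.sum() < 2:
            # coarse grid: fall back to the last two points at or below j
            below = np.flatnonzero(wl <= j)
            if below.size < 2 or post.sum() < 1:
                raise RangeError(
                    f"splice junction {j} nm: not enough points around junction"
                )
            pre = np.zeros_like(pre)
            pre[below[-2:]] = True
        deg = 2 if pre.sum() >= 4 else 1
        coeffs = np.polyfit(wl[pre] - j, refl[pre], deg)
        first_post = np.flatnonzero(post)[0]
        expected = np.polyval(coeffs, wl[first_post] - j)
        refl[post] += expected - refl[first_post]
    prov = dict(spectrum.provenance)
    prov["splice"] = {"junctions": list(sorted(splice_at)), "interval": interval}
    return Spectrum(spectrum.sample_id, wl.copy(), refl, provenance=prov)


def normalize(spectrum: Spectrum, method: str = "snv") -> Spectrum:
    """Per-spectrum normalization: ``snv``, ``minmax`` or ``none``.

    SNV (standard normal variate) centers each spectrum and scales it to
    unit sample standard deviation — the standard chemometric scatter
    correction, and invariant to affine transforms of the input.
    """
    refl = spectrum.reflectance
    if method == "none":
        out = refl.copy()
    elif method == "snv":
        sd = refl.std(ddof=1)
        if sd <= 0 or not np.isfinite(sd):
            raise DegenerateInputError(
                f"SNV: spectrum {spectrum.sample_id!r} has zero variance"
            )
        out = (refl - refl.mean()) / sd
    elif method == "minmax":
        span = refl.max() - refl.min()
        if span <= 0:
            raise DegenerateInputError(
                f"minmax: spectrum {spectrum.sample_id!r} has zero range"
            )
        out = (refl - refl.min()) / span
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    prov = dict(spectrum.provenance)
    prov["normalize"] = method
    return Spectrum(spectrum.sample_id, spectrum.wavelengths.copy(), out, provenance=prov)


def trim_range(spectrum: Spectrum, lo: int = TRIM_LO, hi: int = TRIM_HI) -> Spectrum:
    """Drop the noisy spectral margins, keeping ``lo..hi`` nm inclusive.

    The 350-399 and 2451-2500 nm edges carry instrumental noise and are
    removed; on a 1 nm grid the retained window is exactly 2051 wavelengths.
    """
    wl = spectrum.wavelengths
    if wl.min() > lo or wl.max() < hi:
        raise RangeError(
            f"trim: input grid [{wl.min()}, {wl.max()}] does not cover [{lo}, {hi}]"
        )
    keep = (wl >= lo) & (wl <= hi)
    prov = dict(spectrum.provenance)
    prov["trim"] = {"lo": lo, "hi": hi}
    return Spectrum(spectrum.sample_id, wl[keep], spectrum.reflectance[keep], provenance=prov)


# ---------------------------------------------------------------------------
# Dataset-level IO
# ---------------------------------------------------------------------------

@dataclass
class PreprocessConfig:
    """Options for the fixed-order preprocessing pipeline."""

    resample: bool = True
    splice_at: tuple[int, ...] = DEFAULT_SPLICES
    splice: bool = True
    splice_interval: float = 10.0
    normalize_method: str = "snv"
    trim: bool = True
    trim_lo: int = TRIM_LO
    trim_hi: int = TRIM_HI

    def to_dict(self) -> dict:
        return {
            "resample": self.resample,
            "splice": self.splice,
            "splice_at": list(self.splice_at),
            "splice_interval": self.splice_interval,
            "normalize_method": self.normalize_method,
            "trim": self.trim,
            "trim_lo": self.trim_lo,
            "trim_hi": self.trim_hi,
        }


def _validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.copy()
    required = {"sample_id", "species"}
    missing = required - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("metadata contains duplicate sample_id")
    bad = set(meta["species"]) - set(SPECIES)
    if bad:
        raise ValidationError(f"metadata species outside vocabulary: {sorted(bad)}")
    meta["genus"] = meta["species"].map(GENUS_OF)
    if "region" in meta.columns:
        bad_r = set(meta["region"].dropna()) - set(REGIONS)
        if bad_r:
            raise ValidationError(f"metadata region outside vocabulary: {sorted(bad_r)}")
    if "exposure_week" in meta.columns:
        meta["exposure_week"] = pd.to_numeric(meta["exposure_week"], errors="coerce")
        meta["sample_type"] = np.where(
            meta["exposure_week"].isna(), "intestinal", "exposed"
        )
    else:
        meta["exposure_week"] = np.nan
        meta["sample_type"] = "intestinal"
    return meta


def read_scans_csv(path) -> list[RawScan]:
    """Read a wide spectra CSV: ``sample_id[, scan_index], <nm>, <nm>, ...``."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValidationError("spectra CSV lacks a sample_id column")
    has_scan = "scan_index" in df.columns
    wl_cols = [c for c in df.columns if c not in ("sample_id", "scan_index")]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValidationError(f"non-numeric wavelength column name: {exc}") from exc
    order = np.argsort(wl)
    wl = wl[order]
    wl_cols = [wl_cols[i] for i in order]
    vals = df[wl_cols].to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValidationError("non-numeric reflectance values in spectra CSV")
    scans = []
    for i, row in enumerate(df.itertuples(index=False)):
        scans.append(
            RawScan(
                sample_id=str(getattr(row, "sample_id")),
                scan_index=int(getattr(row, "scan_index")) if has_scan else 1,
                wavelengths=wl,
                reflectance=vals[i],
            )
        )
    return scans


def preprocess_sample(scans: list[RawScan], config: PreprocessConfig) -> Spectrum:
    """Run one sample's scans through the fixed-order pipeline."""
    spec = average_replicates(scans)
    if config.resample:
        spec = resample_to_1nm(spec)
    if config.splice:
        spec = splice_correction(spec, config.splice_at, config.splice_interval)
    spec = normalize(spec, config.normalize_method)
    if config.trim:
        spec = trim_range(spec, config.trim_lo, config.trim_hi)
    return spec


def load_dataset(spectra_path, metadata_path, config: PreprocessConfig | None = None) -> SpectralDataset:
    """Read spectra + metadata CSVs and return the preprocessed dataset.

    Samples present in only one of the two files are dropped with a logged
    report; an empty intersection is an error.
    """
    config = config or PreprocessConfig()
    scans = read_scans_csv(spectra_path)
    meta = _validate_metadata(pd.read_csv(metadata_path))

    by_sample: dict[str, list[RawScan]] = {}
    for s in scans:
        by_sample.setdefault(s.sample_id, []).append(s)

    meta_ids = list(meta["sample_id"].astype(str))
    spec_only = sorted(set(by_sample) - set(meta_ids))
    meta_only = sorted(set(meta_ids) - set(by_sample))
    if spec_only:
        logger.warning("spectra without metadata (dropped): %s", spec_only[:10])
    if meta_only:
        logger.warning("metadata without spectra (dropped): %s", meta_only[:10])
    keep_ids = [sid for sid in meta_ids if sid in by_sample]
    if not keep_ids:
        raise ValidationError("no sample_ids shared between spectra and metadata")

    spectra = [preprocess_sample(by_sample[sid], config) for sid in keep_ids]
    grid = spectra[0].wavelengths
    for sp in spectra[1:]:
        if not np.array_equal(sp.wavelengths, grid):
            raise AlignmentError(f"sample {sp.sample_id!r} on a different grid")
    matrix = np.vstack([sp.reflectance for sp in spectra])
    meta_kept = (
        meta.set_index("sample_id").loc[keep_ids].reset_index()
    )
    provenance = {
        "preprocess": config.to_dict(),
        "order": ["average", "resample", "splice", "normalize", "trim"],
        "n_scans": {sid: len(by_sample[sid]) for sid in keep_ids},
        "dropped_spectra_only": spec_only,
        "dropped_metadata_only": meta_only,
    }
    return SpectralDataset(matrix, grid, meta_kept, provenance)


def preprocess_matrix(dataset: SpectralDataset, config: PreprocessConfig | None = None) -> SpectralDataset:
    """Apply splice/normalize/trim to an already-assembled dataset.

    Used on simulator output, which is already replicate-averaged and on a
    regular grid; resampling is skipped unless requested.
    """
    config = config or PreprocessConfig(resample=False)
    out = []
    for i in range(dataset.n_samples):
        spec = Spectrum(
            str(dataset.metadata["sample_id"].iloc[i]),
            dataset.wavelengths,
            dataset.reflectance[i],
        )
        if config.resample:
            spec = resample_to_1nm(spec)
        if config.splice:
            spec = splice_correction(spec, config.splice_at, config.splice_interval)
        spec = normalize(spec, config.normalize_method)
        if config.trim:
            spec = trim_range(spec, config.trim_lo, config.trim_hi)
        out.append(spec)
    grid = out[0].wavelengths
    matrix = np.vstack([s.reflectance for s in out])
    prov = dict(dataset.provenance)
    prov["preprocess"] = config.to_dict()
    prov["order"] = ["splice", "normalize", "trim"]
    return SpectralDataset(matrix, grid, dataset.metadata.copy(), prov)


def write_dataset(dataset: SpectralDataset, outdir, prefix: str = "processed") -> dict:
    """Write spectra/metadata CSVs plus a JSON provenance sidecar."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wl_cols = [str(int(w)) if float(w).is_integer() else str(w) for w in dataset.wavelengths]
    wide = pd.DataFrame(dataset.reflectance, columns=wl_cols)
    wide.insert(0, "sample_id", dataset.metadata["sample_id"].to_numpy())
    spectra_path = outdir / f"{prefix}_spectra.csv"
    meta_path = outdir / f"{prefix}_metadata.csv"
    prov_path = outdir / f"{prefix}_provenance.json"
    wide.to_csv(spectra_path, index=False)
    dataset.metadata.to_csv(meta_path, index=False)
    from . import __version__

    sidecar = {"package_version": __version__, **dataset.provenance}
    prov_path.write_text(json.dumps(sidecar, indent=2, default=str), encoding="utf-8")
    return {"spectra": str(spectra_path), "metadata": str(meta_path), "provenance": str(prov_path)}
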