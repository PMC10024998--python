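"""Synthetic fecal-NIR data generator.

Emulates the statistical structure the classification analysis assumes:
smooth reflectance spectra on 350-2500 nm with species-specific absorption
features, regional offsets, individual variation, replicate-scan noise,
weathering (exposure) drift — a decline in reflectance over 700-1400 nm and
a rise over ~1500-2500 nm that saturates with exposure time — and
Dirichlet-distributed diet compositions with controllable interspecific
overlap, optionally coupled into the spectra.

Every latent component is returned in a truth record so parameter-recovery
tests never need to re-simulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .spectra import (
    FULL_HI,
    FULL_LO,
    GENUS_OF,
    SPECIES,
    PreprocessConfig,
    SpectralDataset,
    preprocess_matrix,
)


def _smoothstep(x: np.ndarray, edge: float, width: float = 15.0) -> np.ndarray:
    """Logistic step rising at ``edge`` over ~``width`` nm."""
    return 1.0 / (1.0 + np.exp(-(x - edge) / width))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the field design: five microtine species, ~95 pellets
    per species, three replicate scans per pellet, exposure weeks 0-6 for
    the weathered subset.  Amplitudes are on the reflectance scale
    (unitless, baseline ~0.5).
    """

    n_per_species: int = 95
    species: tuple[str, ...] = SPECIES
    regions: tuple[str, ...] = ("WF",)
    wavelength_step: int = 1
    n_features: int = 6
    species_effect_size: float = 0.04
    individual_sd: float = 0.010
    replicate_noise_sd: float = 0.004
    n_scans: int = 3
    exposed_fraction: float = 0.5
    exposure_weeks: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    exposure_decline_amp: float = 0.020
    exposure_rise_amp: float = 0.020
    exposure_saturation: float = 2.0
    region_offset_amp: float = 0.0
    diet_n_taxa: int = 12
    diet_overlap: float = 0.5
    diet_concentration: float = 30.0
    diet_to_spectrum_coupling: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        amps = (
            self.species_effect_size,
            self.individual_sd,
            self.replicate_noise_sd,
            self.exposure_decline_amp,
            self.exposure_rise_amp,
            self.region_offset_amp,
            self.diet_to_spectrum_coupling,
        )
        if any(a < 0 for a in amps):
            raise ValidationError("all simulation amplitudes must be >= 0")
        if not 0.0 <= self.diet_overlap <= 1.0:
            raise ValidationError("diet_overlap must lie in [0, 1]")
        if not 0.0 <= self.exposed_fraction <= 1.0:
            raise ValidationError("exposed_fraction must lie in [0, 1]")
        if self.n_per_species < 1 or self.n_scans < 1:
            raise ValidationError("counts must be positive")
        if self.exposure_saturation <= 0:
            raise ValidationError("exposure_saturation must be > 0")
        unknown = set(self.species) - set(SPECIES)
        if unknown:
            raise ValidationError(f"unknown species codes: {sorted(unknown)}")


def _gaussians(wl: np.ndarray, centers, widths, depths) -> np.ndarray:
    out = np.zeros_like(wl)
    for c, w, d in zip(centers, widths, depths):
        out += d * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return out


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth positive backbone resembling dried plant-material reflectance."""
    x = (wl - FULL_LO) / (FULL_HI - FULL_LO)
    base = 0.45 + 0.12 * np.sin(2.2 * np.pi * x + 0.4) * np.exp(-1.5 * x)
    base += 0.05 * x
    base -= 0.06 * np.exp(-0.5 * ((wl - 1930) / 55.0) ** 2)  # water band
    base -= 0.04 * np.exp(-0.5 * ((wl - 1450) / 45.0) ** 2)
    return base


def exposure_profile(wl: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Unit-saturation spectral signature of weathering.

    Negative plateau over 700-1400 nm, positive plateau over 1500-2500 nm,
    with logistic shoulders so band edges stay smooth.
    """
    decline_band = _smoothstep(wl, 700) * (1 - _smoothstep(wl, 1400))
    rise_band = _smoothstep(wl, 1500)
    return (
        -config.exposure_decline_amp * decline_band
        + config.exposure_rise_amp * rise_band
    )


def saturation(week: float, tau: float) -> float:
    """Saturating exposure response: 0 at week 0, -> 1 as weeks grow."""
    return float(1.0 - np.exp(-week / tau))


def simulate_dataset(
    config: SimulationConfig,
    preprocess: bool = False,
    normalize_method: str = "snv",
):
    """Generate (SpectralDataset, diet RRA DataFrame, truth record).

    The reflectance of sample ``s`` at wavelength ``lam`` is

        baseline(lam) + archetype[species](lam) + offset[region](lam)
        + individual(s, lam) + coupling * diet_component(s, lam)
        + saturation(week) * exposure_profile(lam) + scan noise,

    with scan noise averaged over ``n_scans`` replicates.  With
    ``preprocess=True`` the returned dataset is splice/SNV/trim processed
    and ready for modeling.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    wl = np.arange(FULL_LO, FULL_HI + 1, config.wavelength_step, dtype=float)
    n_wl = wl.size
    species = list(config.species)
    regions = list(config.regions)

    base = _baseline(wl)

    # Species archetypes: sums of Gaussian absorption features at
    # species-specific centers; signed depths so archetypes overlap partially.
    archetypes = {}
    arch_params = {}
    for sp in species:
        centers = rng.uniform(450, 2400, size=config.n_features)
        widths = rng.uniform(25, 90, size=config.n_features)
        depths = config.species_effect_size * rng.uniform(0.5, 1.0, size=config.n_features)
        depths *= rng.choice([-1.0, 1.0], size=config.n_features)
        archetypes[sp] = _gaussians(wl, centers, widths, depths)
        arch_params[sp] = {
            "centers": centers.tolist(),
            "widths": widths.tolist(),
            "depths": depths.tolist(),
        }

    # Regional offsets: small shared spectral shifts per region (first region
    # is the reference with zero offset).
    region_offsets = {regions[0]: np.zeros(n_wl)}
    for rg in regions[1:]:
        centers = rng.uniform(450, 2400, size=4)
        widths = rng.uniform(60, 160, size=4)
        depths = config.region_offset_amp * rng.uniform(0.5, 1.0, size=4)
        depths *= rng.choice([-1.0, 1.0], size=4)
        region_offsets[rg] = _gaussians(wl, centers, widths, depths)

    # Diet alphabet: Dirichlet parameters per species pulled toward a common
    # mean as overlap -> 1, plus smooth spectral signatures per taxon.
    common_p = rng.dirichlet(np.full(config.diet_n_taxa, 2.0))
    diet_p = {}
    for sp in species:
        own = rng.dirichlet(np.full(config.diet_n_taxa, 1.2))
        diet_p[sp] = (1 - config.diet_overlap) * own + config.diet_overlap * common_p
    taxon_sig = np.zeros((config.diet_n_taxa, n_wl))
    for t in range(config.diet_n_taxa):
        centers = rng.uniform(450, 2400, size=3)
        widths = rng.uniform(40, 120, size=3)
        depths = rng.uniform(-1.0, 1.0, size=3)
        taxon_sig[t] = _gaussians(wl, centers, widths, depths)

    rows = []
    refl = []
    diet_rows = []
    individual = []
    counter = 0
    n_exposed = int(round(config.exposed_fraction * config.n_per_species))
    weeks_cycle = list(config.exposure_weeks)
    for rg in regions:
        for sp in species:
            for k in range(config.n_per_species):
                sid = f"{rg}_{sp}_{k:03d}"
                exposed = k < n_exposed
                week = weeks_cycle[k % len(weeks_cycle)] if exposed else None
                indiv = np.zeros(n_wl)
                if config.individual_sd > 0:
                    c = rng.uniform(450, 2400, size=3)
                    w = rng.uniform(80, 200, size=3)
                    d = rng.normal(0.0, config.individual_sd, size=3)
                    indiv = _gaussians(wl, c, w, d)
                diet = rng.dirichlet(config.diet_concentration * diet_p[sp])
                spectrum = base + archetypes[sp] + region_offsets[rg] + indiv
                if config.diet_to_spectrum_coupling > 0:
                    spectrum = spectrum + config.diet_to_spectrum_coupling * (
                        (diet - common_p) @ taxon_sig
                    )
                if week is not None:
                    spectrum = spectrum + saturation(
                        week, config.exposure_saturation
                    ) * exposure_profile(wl, config)
                if config.replicate_noise_sd > 0:
                    noise = rng.normal(
                        0.0, config.replicate_noise_sd, size=(config.n_scans, n_wl)
                    ).mean(axis=0)
                else:
                    noise = 0.0
                refl.append(np.clip(spectrum + noise, 1e-4, 1.5 - 1e-9))
                rows.append(
                    {
                        "sample_id": sid,
                        "species": sp,
                        "genus": GENUS_OF[sp],
                        "region": rg,
                        "exposure_week": np.nan if week is None else week,
                        "sample_type": "intestinal" if week is None else "exposed",
                    }
                )
                diet_rows.append(diet)
                individual.append(indiv)
                counter += 1

    metadata = pd.DataFrame(rows)
    dataset = SpectralDataset(
        np.vstack(refl),
        wl,
        metadata,
        provenance={"simulated": True, "config": asdict(config)},
    )
    diet = pd.DataFrame(
        np.vstack(diet_rows),
        columns=[f"taxon_{t:02d}" for t in range(config.diet_n_taxa)],
    )
    diet.insert(0, "sample_id", metadata["sample_id"])
    truth = {
        "config": asdict(config),
        "wavelengths": wl,
        "baseline": base,
        "archetypes": archetypes,
        "archetype_params": arch_params,
        "region_offsets": region_offsets,
        "individual_effects": np.vstack(individual),
        "exposure_profile": exposure_profile(wl, config),
        "diet_means": diet_p,
        "diet_common_mean": common_p,
        "taxon_signatures": taxon_sig,
    }
    if preprocess:
        dataset = preprocess_matrix(
            dataset,
            PreprocessConfig(resample=False, normalize_method=normalize_method),
        )
    return dataset, diet, truth


def simulate_scan_table(config: SimulationConfig) -> pd.DataFrame:
    """Wide per-scan table (``n_scans`` rows per sample) for the IO pipeline.

    Reuses :func:`simulate_dataset` for the clean part and re-adds per-scan
    noise, so replicate averaging can be exercised end to end.
    """
    clean_cfg = SimulationConfig(**{**asdict(config), "replicate_noise_sd": 0.0})
    dataset, _, _ = simulate_dataset(clean_cfg)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 7919]))
    wl_cols = [str(int(w)) for w in dataset.wavelengths]
    recs = []
    for i in range(dataset.n_samples):
        for scan in range(1, config.n_scans + 1):
            noisy = dataset.reflectance[i] + rng.normal(
                0.0, config.replicate_noise_sd, size=dataset.wavelengths.size
            )
            rec = {"sample_id": dataset.metadata["sample_id"].iloc[i], "scan_index": scan}
            rec.update(dict(zip(wl_cols, np.clip(noisy, 1e-4, 1.5 - 1e-9))))
            recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Named fixtures
# ---------------------------------------------------------------------------

#: Versioned fixture configurations with fixed seeds.  All use a 10 nm grid
#: to keep test runtimes at desk scale; the generative structure is the same
#: as at full resolution.
FIXTURES: dict[str, SimulationConfig] = {
    "separable-5species": SimulationConfig(
        n_per_species=42,
        wavelength_step=10,
        species_effect_size=0.05,
        individual_sd=0.008,
        replicate_noise_sd=0.003,
        exposed_fraction=1.0,
        rng_seed=20230319,
    ),
    "wf-ef-transfer": SimulationConfig(
        n_per_species=45,
        species=("Mruf", "Moec"),
        regions=("WF", "EF"),
        wavelength_step=10,
        species_effect_size=0.045,
        individual_sd=0.008,
        replicate_noise_sd=0.003,
        exposed_fraction=0.0,
        region_offset_amp=0.09,
        rng_seed=20230320,
    ),
    "exposure-grid": SimulationConfig(
        n_per_species=36,
        species=("Llem", "Mruf", "Moec", "Magr"),
        wavelength_step=10,
        species_effect_size=0.05,
        individual_sd=0.008,
        replicate_noise_sd=0.003,
        exposed_fraction=2.0 / 3.0,
        exposure_weeks=(1, 2, 3, 4, 5, 6),
        rng_seed=20230321,
    ),
    "null-diet": SimulationConfig(
        n_per_species=20,
        wavelength_step=10,
        species_effect_size=0.04,
        individual_sd=0.008,
        replicate_noise_sd=0.003,
        exposed_fraction=0.0,
        diet_overlap=1.0,
        diet_to_spectrum_coupling=0.0,
        rng_seed=20230322,
    ),
}


def make_fixture(name: str, preprocess: bool = True):
    """Return the named, seeded fixture as (dataset, diet, truth)."""
    if name not in FIXTURES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        )
    return simulate_dataset(FIXTURES[name], preprocess=preprocess)
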