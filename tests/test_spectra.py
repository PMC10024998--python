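"""Preprocessing: replicate averaging, interpolation, splice, SNV, trimming."""

import numpy as np
import pandas as pd
import pytest

from pelletspec import (
    PreprocessConfig,
    RawScan,
    Spectrum,
    average_replicates,
    load_dataset,
    normalize,
    resample_to_1nm,
    splice_correction,
    trim_range,
)
from pelletspec.exceptions import (
    AlignmentError,
    DegenerateInputError,
    RangeError,
    ValidationError,
)
from pelletspec.simulate import SimulationConfig, simulate_scan_table

WL = np.arange(350.0, 2501.0)


def _scan(refl, sid="s1", idx=1, wl=WL):
    return RawScan(sid, idx, wl, refl)


def _smooth(wl):
    return 0.5 + 0.05 * np.sin(2 * np.pi * (wl - 350) / 4300.0)


class TestAverageReplicates:
    def test_identical_scans_reproduce_spectrum(self):
        refl = _smooth(WL)
        out = average_replicates([_scan(refl, idx=i) for i in (1, 2, 3)])
        np.testing.assert_array_equal(out.reflectance, refl)

    def test_pointwise_mean(self):
        wl = np.array([500.0, 600.0])
        scans = [
            _scan(np.array([0.2, 0.5]), idx=1, wl=wl),
            _scan(np.array([0.4, 0.5]), idx=2, wl=wl),
            _scan(np.array([0.6, 0.5]), idx=3, wl=wl),
        ]
        out = average_replicates(scans)
        assert out.reflectance[0] == pytest.approx(0.4)

    def test_random_scans_match_loop_oracle(self, rng):
        scans = [_scan(rng.uniform(0.1, 0.9, WL.size), idx=i) for i in (1, 2, 3)]
        out = average_replicates(scans)
        # independent elementwise loop
        expected = np.array(
            [sum(s.reflectance[j] for s in scans) / 3 for j in range(WL.size)]
        )
        np.testing.assert_allclose(out.reflectance, expected, rtol=0, atol=1e-15)
        assert out.provenance["n_scans"] == 3

    def test_mismatched_grids_name_the_sample(self):
        a = _scan(_smooth(WL))
        b = RawScan("s1", 2, WL + 1.0, _smooth(WL + 1.0))
        with pytest.raises(AlignmentError, match="s1"):
            average_replicates([a, b])


class TestResample:
    def test_integer_grid_unchanged(self):
        refl = _smooth(WL)
        out = resample_to_1nm(_scan(refl))
        np.testing.assert_allclose(out.reflectance, refl, atol=1e-15)
        np.testing.assert_array_equal(out.wavelengths, WL)

    def test_linear_ramp_interpolates_exactly(self):
        wl = np.arange(350.0, 2501.0, 2.5)  # last point lands on 2500.0
        refl = 0.1 + 1e-4 * (wl - 350.0)
        out = resample_to_1nm(RawScan("s", 1, wl, refl))
        np.testing.assert_allclose(
            out.reflectance, 0.1 + 1e-4 * (out.wavelengths - 350.0), atol=1e-12
        )

    def test_random_piecewise_linear_matches_closed_form(self, rng):
        knots = np.sort(rng.uniform(351, 2499, 60))
        wl = np.concatenate([[350.0], knots, [2500.0]])
        refl = rng.uniform(0.2, 0.8, wl.size)
        out = resample_to_1nm(RawScan("s", 1, wl, refl))
        probes = rng.integers(351, 2500, 10)
        for p in probes:
            i = np.searchsorted(wl, p) - 1
            frac = (p - wl[i]) / (wl[i + 1] - wl[i])
            expected = refl[i] + frac * (refl[i + 1] - refl[i])
            got = out.reflectance[out.wavelengths == p][0]
            assert got == pytest.approx(expected, abs=1e-12)

    def test_grid_outside_support_raises(self):
        wl = np.arange(400.0, 2501.0)
        with pytest.raises(RangeError):
            resample_to_1nm(RawScan("s", 1, wl, _smooth(wl)))


class TestSpliceCorrection:
    def test_continuous_spectrum_unchanged(self):
        spec = Spectrum("s", WL, _smooth(WL))
        out = splice_correction(spec)
        np.testing.assert_allclose(out.reflectance, spec.reflectance, atol=1e-9)

    def test_single_step_removed(self):
        refl = _smooth(WL) + 0.05 * (WL > 1000)
        out = splice_correction(Spectrum("s", WL, refl))
        np.testing.assert_allclose(out.reflectance, _smooth(WL), atol=1e-6)

    def test_two_steps_removed(self):
        refl = _smooth(WL) + 0.05 * (WL > 1000) - 0.03 * (WL > 1830)
        out = splice_correction(Spectrum("s", WL, refl))
        np.testing.assert_allclose(out.reflectance, _smooth(WL), atol=1e-6)

    def test_junction_at_edge_raises(self):
        spec = Spectrum("s", WL, _smooth(WL))
        with pytest.raises(RangeError):
            splice_correction(spec, splice_at=(350,))


class TestNormalize:
    def test_snv_zero_mean_unit_sd(self, rng):
        spec = Spectrum("s", WL, rng.uniform(0.2, 0.9, WL.size))
        out = normalize(spec, "snv")
        assert out.reflectance.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.reflectance.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_snv_affine_invariance(self, rng):
        refl = rng.uniform(0.2, 0.9, WL.size)
        a = normalize(Spectrum("s", WL, refl), "snv")
        b = normalize(Spectrum("s", WL, 0.37 * refl + 0.11), "snv")
        np.testing.assert_allclose(a.reflectance, b.reflectance, atol=1e-9)

    def test_snv_matches_two_pass_loop(self, rng):
        refl = rng.uniform(0.2, 0.9, 200)
        wl = np.arange(200.0)
        out = normalize(Spectrum("s", wl, refl), "snv")
        m = sum(refl) / refl.size
        var = sum((x - m) ** 2 for x in refl) / (refl.size - 1)
        expected = (refl - m) / np.sqrt(var)
        np.testing.assert_allclose(out.reflectance, expected, atol=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(DegenerateInputError):
            normalize(Spectrum("s", WL, np.full(WL.size, 0.5)), "snv")

    def test_minmax_range(self, rng):
        out = normalize(Spectrum("s", WL, rng.uniform(0.2, 0.9, WL.size)), "minmax")
        assert out.reflectance.min() == pytest.approx(0.0)
        assert out.reflectance.max() == pytest.approx(1.0)

    def test_unknown_method_raises(self):
        with pytest.raises(ValidationError):
            normalize(Spectrum("s", WL, _smooth(WL)), "area")


class TestTrim:
    def test_2151_to_2051_points(self):
        out = trim_range(Spectrum("s", WL, _smooth(WL)))
        assert WL.size == 2151
        assert out.wavelengths.size == 2051

    def test_boundaries_preserved_exactly(self):
        refl = _smooth(WL)
        out = trim_range(Spectrum("s", WL, refl))
        assert out.wavelengths[0] == 400 and out.wavelengths[-1] == 2450
        assert out.reflectance[0] == refl[WL == 400][0]
        assert out.reflectance[-1] == refl[WL == 2450][0]

    def test_only_margins_removed(self):
        out = trim_range(Spectrum("s", WL, _smooth(WL)))
        removed = np.setdiff1d(WL, out.wavelengths)
        assert np.all(((removed >= 350) & (removed <= 399))
                      | ((removed >= 2451) & (removed <= 2500)))

    def test_missing_retained_range_raises(self):
        wl = np.arange(500.0, 2000.0)
        with pytest.raises(RangeError):
            trim_range(Spectrum("s", wl, _smooth(wl)))

    def test_trim_idempotent(self):
        once = trim_range(Spectrum("s", WL, _smooth(WL)))
        twice = trim_range(once)
        np.testing.assert_array_equal(once.reflectance, twice.reflectance)


def test_snv_idempotent_within_tolerance(rng):
    spec = Spectrum("s", WL, rng.uniform(0.2, 0.9, WL.size))
    once = normalize(spec, "snv")
    twice = normalize(once, "snv")
    np.testing.assert_allclose(once.reflectance, twice.reflectance, atol=1e-9)


@pytest.fixture(scope="module")
def csv_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("io")
    cfg = SimulationConfig(
        n_per_species=3, species=("Llem", "Mruf"), wavelength_step=10,
        replicate_noise_sd=0.002, rng_seed=3,
    )
    scans = simulate_scan_table(cfg)
    scans.to_csv(d / "scans.csv", index=False)
    meta = scans[["sample_id"]].drop_duplicates().reset_index(drop=True)
    meta["species"] = [sid.split("_")[1] for sid in meta["sample_id"]]
    meta["region"] = "WF"
    meta["exposure_week"] = [0, 1, None, 2, None, 3]
    meta.to_csv(d / "meta.csv", index=False)
    return d / "scans.csv", d / "meta.csv"


class TestLoadDataset:
    def test_pipeline_produces_2051_grid(self, csv_paths):
        ds = load_dataset(*csv_paths)
        assert ds.wavelengths[0] == 400 and ds.wavelengths[-1] == 2450
        assert ds.wavelengths.size == 2051
        assert np.all(np.isfinite(ds.reflectance))
        assert ds.n_samples == 6
        # SNV happens before trimming, so post-trim row means are near but
        # not exactly zero
        assert np.all(np.abs(ds.reflectance.mean(axis=1)) < 0.2)

    def test_metadata_derivations(self, csv_paths):
        ds = load_dataset(*csv_paths)
        assert set(ds.metadata["genus"]) == {"Lemmus", "Myodes"}
        intest = ds.metadata["exposure_week"].isna()
        assert (ds.metadata.loc[intest, "sample_type"] == "intestinal").all()

    def test_two_runs_bit_identical(self, csv_paths):
        a = load_dataset(*csv_paths)
        b = load_dataset(*csv_paths)
        assert np.array_equal(a.reflectance, b.reflectance)

    def test_duplicate_sample_id_rejected(self, csv_paths, tmp_path):
        spectra_path, meta_path = csv_paths
        meta = pd.read_csv(meta_path)
        bad = pd.concat([meta, meta.iloc[[0]]])
        bad.to_csv(tmp_path / "dup.csv", index=False)
        with pytest.raises(ValidationError, match="duplicate"):
            load_dataset(spectra_path, tmp_path / "dup.csv")

    def test_unknown_species_rejected(self, csv_paths, tmp_path):
        spectra_path, meta_path = csv_paths
        meta = pd.read_csv(meta_path)
        meta.loc[0, "species"] = "Mmus"
        meta.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(ValidationError, match="vocabulary"):
            load_dataset(spectra_path, tmp_path / "bad.csv")


def test_subset_keeps_rows_and_metadata_aligned(separable, rng):
    ds, _, _ = separable
    perm = rng.permutation(ds.n_samples)
    shuffled = ds.subset(perm)
    for i, j in enumerate(perm[:20]):
        assert shuffled.metadata["sample_id"].iloc[i] == ds.metadata["sample_id"].iloc[j]
        np.testing.assert_array_equal(shuffled.reflectance[i], ds.reflectance[j])
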