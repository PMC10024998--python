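"""rdMCCV framework: stratified splits, iteration bookkeeping, IPA, transfer."""

import numpy as np
import pandas as pd
import pytest

from pelletspec import (
    ModelSpec,
    MonteCarloCV,
    SplitScheme,
    aggregate_importance,
    compute_ipa,
    run_rdmccv,
    stratified_split,
    transfer_predict,
)
from pelletspec.exceptions import StratificationError, ValidationError


def _meta(n_per, species=("Llem", "Mruf"), weeks=None):
    rows = []
    for sp in species:
        for i in range(n_per):
            rows.append({
                "sample_id": f"{sp}_{i:03d}", "species": sp,
                "exposure_week": None if weeks is None else weeks[i % len(weeks)],
            })
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_stratum_of_20_at_5pct_gives_one_test_sample(self, rng):
        meta = _meta(20, species=("Llem",))
        cal, test = stratified_split(meta, 0.05, ("species",), rng)
        assert len(test) == 1
        assert len(cal) == 19

    def test_split_is_an_exact_partition(self, rng):
        meta = _meta(17, species=("Llem", "Mruf", "Moec"), weeks=[0, 1, 2])
        for fraction in (0.05, 0.1, 0.2, 0.5):
            cal, test = stratified_split(
                meta, fraction, ("species", "exposure_week"), rng
            )
            assert set(cal) | set(test) == set(meta["sample_id"])
            assert set(cal) & set(test) == set()

    def test_per_stratum_share_close_to_fraction(self, rng):
        meta = _meta(100, species=("Llem", "Mruf", "Mrut", "Moec", "Magr"),
                     weeks=[0, 1, 2, 3, 4, 5, 6])
        cal, test = stratified_split(meta, 0.2, ("species", "exposure_week"), rng)
        test_set = set(test)
        strata = meta.groupby(
            ["species", "exposure_week"])["sample_id"].apply(list)
        for members in strata:
            n_test = sum(m in test_set for m in members)
            assert abs(n_test - 0.2 * len(members)) <= 1

    def test_small_stratum_kept_in_calibration(self, rng, caplog):
        meta = _meta(10, species=("Llem",))
        meta = pd.concat(
            [meta, pd.DataFrame([{"sample_id": "Mruf_000", "species": "Mruf",
                                  "exposure_week": None}])],
            ignore_index=True,
        )
        with caplog.at_level("WARNING"):
            cal, test = stratified_split(meta, 0.2, ("species",), rng)
        assert "Mruf_000" in cal
        assert any("stratum" in r.message for r in caplog.records)

    def test_small_stratum_strict_raises(self, rng):
        meta = _meta(10, species=("Llem",))
        meta = pd.concat(
            [meta, pd.DataFrame([{"sample_id": "Mruf_000", "species": "Mruf",
                                  "exposure_week": None}])],
            ignore_index=True,
        )
        with pytest.raises(StratificationError):
            stratified_split(meta, 0.2, ("species",), rng, strict=True)

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(ValidationError):
            stratified_split(_meta(10), 1.2, ("species",), rng)


@pytest.fixture(scope="module")
def small_run(separable):
    ds, _, _ = separable
    spec = ModelSpec(degree=1, max_terms=13)
    scheme = SplitScheme(
        fractions=(0.1, 0.2), iterations_per_fraction=6,
        stratify_by=("species", "exposure_week"), rng_seed=7,
    )
    return MonteCarloCV(ds, spec, scheme).run(), ds, spec, scheme


class TestRunRdmccv:
    def test_model_count_equals_fractions_times_iterations(self, small_run):
        result, _, _, scheme = small_run
        assert result.n_models + len(result.skipped) == scheme.total_models
        assert result.n_models == 12

    def test_default_scheme_totals_600_models(self):
        assert SplitScheme().total_models == 600

    def test_separable_fixture_low_misclassification(self, small_run):
        result, *_ = small_run
        assert result.iterations["mcr"].mean() <= 0.05

    def test_class_accuracy_identity(self, small_run):
        """Test-count-weighted class recall + misclassification rate = 1."""
        result, *_ = small_run
        for (frac, rep), grp in result.class_accuracy.groupby(["fraction", "replicate"]):
            grp = grp.dropna(subset=["accuracy"])
            weighted = (grp["accuracy"] * grp["n_test"]).sum() / grp["n_test"].sum()
            it = result.iterations.query("fraction == @frac and replicate == @rep")
            assert weighted + it["mcr"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_named_iteration_reproducible(self, small_run):
        result, ds, spec, scheme = small_run
        rng = scheme.iteration_rng(1, 3)  # fraction 0.2, replicate 3
        cal, test = stratified_split(ds.metadata, 0.2, scheme.stratify_by, rng)
        recorded = result.records.query("fraction == 0.2 and replicate == 3")
        assert sorted(recorded["sample_id"]) == sorted(test)

    def test_every_exposure_week_in_every_calibration_set(self, small_run):
        result, ds, spec, scheme = small_run
        weeks = set(ds.metadata["exposure_week"].dropna())
        meta = ds.metadata.set_index("sample_id")
        for fi, frac in enumerate(scheme.fractions):
            for rep in range(scheme.iterations_per_fraction):
                rng = scheme.iteration_rng(fi, rep)
                cal, _ = stratified_split(ds.metadata, frac, scheme.stratify_by, rng)
                assert set(meta.loc[cal, "exposure_week"].dropna()) == weeks

    def test_missing_class_iterations_flagged_not_dropped(self, separable):
        ds, _, _ = separable
        # single Mrut sample + species-blind stratification => Mrut sometimes
        # lands in the test set, leaving calibration without the class
        keep = (ds.metadata["species"] != "Mrut").to_numpy()
        keep[np.flatnonzero(~keep)[0]] = True
        sub = ds.subset(keep)
        scheme = SplitScheme(fractions=(0.5,), iterations_per_fraction=8,
                             stratify_by=(), rng_seed=1)
        result = run_rdmccv(sub, ModelSpec(degree=1, max_terms=9), scheme)
        assert result.n_models + len(result.skipped) == 8
        assert len(result.skipped) >= 1
        assert all("Mrut" in s["missing_classes"] for s in result.skipped)

    def test_vi_counts_bounded_by_iterations(self, small_run):
        result, *_ = small_run
        assert np.all(result.vi_counts >= 0)
        assert np.all(result.vi_counts <= result.n_models)

    def test_csv_round_trip_preserves_ipa(self, small_run, tmp_path):
        result, *_ = small_run
        result.to_csvs(tmp_path)
        reread = pd.read_csv(tmp_path / "outcomes.csv")
        ipa_disk = compute_ipa(reread).set_index("sample_id")["ipa"]
        ipa_mem = result.ipa().set_index("sample_id")["ipa"]
        pd.testing.assert_series_equal(ipa_disk, ipa_mem)


class TestComputeIpa:
    def test_always_correct_gives_one(self):
        rec = pd.DataFrame({"sample_id": ["a"] * 5, "correct": [1] * 5})
        assert compute_ipa(rec)["ipa"].iloc[0] == 1.0

    def test_three_of_four(self):
        rec = pd.DataFrame({"sample_id": ["a"] * 4, "correct": [1, 1, 1, 0]})
        out = compute_ipa(rec)
        assert out["ipa"].iloc[0] == 0.75
        assert out["n_tested"].iloc[0] == 4

    def test_matches_groupby_oracle(self, small_run):
        result, *_ = small_run
        out = result.ipa().set_index("sample_id")["ipa"]
        brute = {}
        for sid in result.records["sample_id"].unique():
            vals = result.records.loc[result.records["sample_id"] == sid, "correct"]
            brute[sid] = sum(vals) / len(vals)
        for sid, v in brute.items():
            assert out[sid] == pytest.approx(v, abs=1e-15)


class TestAggregateImportance:
    def test_counts(self):
        vi = np.array([[0.0, 5.0, 0.0], [0.0, 3.0, 1.0], [0.0, 0.0, 2.0]])
        np.testing.assert_array_equal(aggregate_importance(vi), [0, 2, 2])


class TestTransferPredict:
    def test_region_offset_degrades_external_prediction(self, transfer):
        ds, _, _ = transfer
        out = transfer_predict(ds, "WF", ModelSpec(degree=2, max_terms=15))
        assert out["per_region"]["EF"]["mcr"] > out["per_region"]["WF"]["mcr"]
        assert out["per_region"]["WF"]["role"] == "calibration"

    def test_no_region_offset_means_exchangeable_regions(self):
        from pelletspec import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_per_species=20, species=("Mruf", "Moec"), regions=("WF", "EF"),
            wavelength_step=10, region_offset_amp=0.0, exposed_fraction=0.0,
            species_effect_size=0.05, individual_sd=0.008,
            replicate_noise_sd=0.003, rng_seed=9,
        )
        ds, _, _ = simulate_dataset(cfg, preprocess=True)
        out = transfer_predict(ds, "WF", ModelSpec(degree=1, max_terms=15))
        assert abs(out["per_region"]["EF"]["mcr"]
                   - out["per_region"]["WF"]["mcr"]) <= 0.1

    def test_unknown_region_rejected(self, transfer):
        ds, _, _ = transfer
        with pytest.raises(ValidationError):
            transfer_predict(ds, "XX", ModelSpec())
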