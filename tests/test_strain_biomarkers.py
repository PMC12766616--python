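import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from strainhet.strain_biomarkers import (apply_qc, assess_missing_segment_impact,
                                         cohort_outlier_fences, global_strain,
                                         standardize, strain_cov,
                                         validate_sign)
from oracles import cov_oracle


@pytest.mark.parametrize("value,direction,expected", [
    (-18.1, "longitudinal", True),
    (+5.0, "longitudinal", False),    # positive longitudinal is non-sensical
    (-3.0, "radial", False),          # negative radial is non-sensical
    (-17.2, "circumferential", True),
    (+2.0, "circumferential", False),
    (+31.0, "radial", True),
    (0.0, "radial", False),
    (float("nan"), "longitudinal", False),
])
def test_sign_validity_convention(value, direction, expected):
    assert validate_sign(value, direction) is expected


def test_sign_validity_vectorized():
    out = validate_sign(np.array([-18.0, 5.0, np.nan]), "longitudinal")
    assert out.tolist() == [True, False, False]


def test_sign_validity_rejects_unknown_direction():
    with pytest.raises(ValueError):
        validate_sign(1.0, "torsional")


class TestOutlierFences:
    def test_hand_arithmetic(self):
        # Q1=16, Q3=20 -> IQR 4 -> fences 16-12, 20+12
        lo, hi = cohort_outlier_fences([16, 16, 20, 20])
        assert (lo, hi) == (4.0, 32.0)

    def test_interpolated_quartiles(self):
        lo, hi = cohort_outlier_fences(np.arange(1, 101))
        assert lo == pytest.approx(25.75 - 3 * 49.5)
        assert hi == pytest.approx(75.25 + 3 * 49.5)

    def test_degenerate_spread(self):
        lo, hi = cohort_outlier_fences([7.0] * 10)
        assert lo == hi == 7.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            cohort_outlier_fences([1.0, 2.0, 3.0])


class TestGlobalStrain:
    @pytest.mark.parametrize("values,expected", [
        ([20.0] * 16, 20.0),
        ([10, 20, 30], 20.0),
        ([15] * 8 + [25] * 8, 20.0),
        ([-15] * 8 + [-25] * 8, 20.0),   # absolute-value convention
    ])
    def test_mean_absolute(self, values, expected):
        assert global_strain(values) == pytest.approx(expected)

    def test_empty_is_missing(self):
        assert math.isnan(global_strain([]))


class TestStrainCov:
    def test_zero_dispersion(self):
        assert strain_cov([18.0] * 16) == 0.0

    def test_hand_arithmetic_half_split(self):
        values = [15.0] * 8 + [25.0] * 8
        # SD = sqrt(16*25/15), mean = 20
        expected = math.sqrt(400.0 / 15.0) / 20.0
        assert strain_cov(values) == pytest.approx(expected, abs=1e-12)
        assert strain_cov(values) == pytest.approx(0.2582, abs=1e-4)

    def test_too_few_segments_missing(self):
        assert math.isnan(strain_cov([18.0] * 6))
        assert not math.isnan(strain_cov([18.0] * 7))

    def test_population_sd_switch(self):
        values = [15.0] * 8 + [25.0] * 8
        assert strain_cov(values, ddof=0) == pytest.approx(5.0 / 20.0)

    @given(st.lists(st.floats(5.0, 50.0), min_size=7, max_size=16),
           st.floats(0.1, 10.0))
    @settings(max_examples=60, deadline=None)
    def test_scale_and_permutation_invariance(self, values, c):
        base = strain_cov(values)
        scaled = strain_cov([c * v for v in values])
        permuted = strain_cov(values[::-1])
        assert scaled == pytest.approx(base, rel=1e-9)
        assert permuted == pytest.approx(base, rel=1e-12)

    @given(st.lists(st.floats(5.0, 50.0), min_size=7, max_size=16))
    @settings(max_examples=60, deadline=None)
    def test_matches_direct_formula(self, values):
        assert strain_cov(values) == pytest.approx(cov_oracle(values),
                                                   abs=1e-12)

    def test_cov_times_mean_is_sd(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(10, 30, 16)
        assert strain_cov(v) * v.mean() == pytest.approx(v.std(ddof=1))

    def test_perturbing_one_segment_raises_cov(self):
        base = [20.0] * 16
        perturbed = [20.0] * 15 + [14.0]
        assert strain_cov(perturbed) > strain_cov(base)


class TestStandardize:
    def test_hand_example(self):
        assert standardize([1, 2, 3]).tolist() == [-1.0, 0.0, 1.0]

    def test_moments_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 3, 50)
        z = standardize(x)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1)
        np.testing.assert_allclose(standardize(2.5 * x + 7), z, atol=1e-10)

    def test_missing_propagates(self):
        z = standardize([1.0, np.nan, 3.0])
        assert math.isnan(z[1]) and not math.isnan(z[0])

    def test_zero_spread_errors(self):
        with pytest.raises(ValueError):
            standardize([2.0, 2.0, 2.0])


class TestMissingSegmentImpact:
    def test_full_set_no_bias(self):
        rng = np.random.default_rng(2)
        v = rng.uniform(10, 30, 16)
        table = assess_missing_segment_impact(v, k_range=[16])
        assert table.loc[0, "bias"] == pytest.approx(0, abs=1e-14)
        assert table.loc[0, "sd"] == pytest.approx(0, abs=1e-14)

    def test_equal_valued_set(self):
        table = assess_missing_segment_impact([20.0] * 16, k_range=[4, 8, 12])
        assert (table["mean_cov"] == 0).all()

    def test_exhaustive_matches_enumeration(self):
        v = np.array([15.0] * 8 + [25.0] * 8)
        table = assess_missing_segment_impact(v, k_range=[8], n_draws=13000)
        assert table.loc[0, "exhaustive"]
        covs = [cov_oracle(sub) for sub in itertools.combinations(v, 8)]
        assert table.loc[0, "mean_cov"] == pytest.approx(np.mean(covs))
        assert table.loc[0, "sd"] == pytest.approx(np.std(covs))

    def test_small_k_errors(self):
        with pytest.raises(ValueError):
            assess_missing_segment_impact([20.0] * 16, k_range=[1])


def _clean_long(n=40, seed=0):
    from strainhet.synthetic_cohort import SimulationConfig, simulate_cohort
    cfg = SimulationConfig(n_participants=n, seed=seed)
    return simulate_cohort(cfg).strain_long


class TestApplyQC:
    def test_clean_cohort_passes_untouched(self):
        # noise-free cohort: no wrong signs, no outliers possible
        from strainhet.synthetic_cohort import SimulationConfig, simulate_cohort
        cfg = SimulationConfig(
            n_participants=30, seed=1,
            between_segment_sd={"longitudinal": 0.5, "circumferential": 0.5,
                                "radial": 0.5},
            between_participant_sd={"longitudinal": 0.5,
                                    "circumferential": 0.5, "radial": 0.5})
        cohort = simulate_cohort(cfg)
        _, bm, report = apply_qc(cohort.strain_long)
        assert report.inclusion_fraction == 1.0
        assert report.n_bad_sign == 0
        assert bm["cov_cs"].notna().all()

    def test_six_valid_segments_blocks_cov(self):
        rows = []
        # 50 background participants so cohort fences are defined
        for pid in range(50):
            for seg in range(1, 17):
                rows.append({"participant_id": pid, "direction":
                             "circumferential", "segment": seg,
                             "value": -18.0 - 0.05 * seg - 0.01 * pid})
        for seg in range(1, 17):
            rows.append({"participant_id": 99, "direction": "circumferential",
                         "segment": seg,
                         "value": -18.5 if seg <= 6 else np.nan})
        _, bm, _ = apply_qc(pd.DataFrame(rows))
        row = bm[bm["participant_id"] == 99].iloc[0]
        assert row["n_valid_circumferential"] == 6
        assert math.isnan(row["cov_cs"])
        assert not math.isnan(row["gcs"])     # global strain still computed
        assert "too_few_segments" in row["qc_flags_circumferential"]

    def test_flags_cover_injected_sign_flips(self, small_cohort,
                                             small_biomarkers):
        clean, _, _ = small_biomarkers
        ledger = small_cohort.ledger
        flips = ledger[ledger["kind"] == "sign_flip"]
        merged = flips.merge(clean, on=["participant_id", "direction",
                                        "segment"])
        # flipping a valid value produces a wrong sign -> must be invalid
        assert (~merged["valid"]).mean() >= 0.95

    def test_idempotent_on_cleaned_data(self, small_cohort, small_biomarkers):
        clean, bm1, _ = small_biomarkers
        rerun_input = clean.copy()
        rerun_input.loc[~rerun_input["valid"], "value"] = np.nan
        rerun_input = rerun_input[["participant_id", "direction", "segment",
                                   "value"]]
        _, bm2, _ = apply_qc(rerun_input)
        pd.testing.assert_frame_equal(
            bm1.drop(columns=[c for c in bm1.columns if "qc_flags" in c]),
            bm2.drop(columns=[c for c in bm2.columns if "qc_flags" in c]))

    def test_empty_cohort_errors(self):
        empty = pd.DataFrame(columns=["participant_id", "direction",
                                      "segment", "value"])
        with pytest.raises(ValueError):
            apply_qc(empty)
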