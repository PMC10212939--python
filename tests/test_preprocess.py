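import numpy as np
import pandas as pd
import pytest
from scipy import stats

import donorscreen as ds
from donorscreen.preprocess import (
    MASK_GAUSSIAN, MASK_LVCF, MASK_OBSERVED, MASK_UNSET, N_BLOCKS,
    Standardization, default_anchors, frame_to_tensor, normal_range_sigma,
    tensor_to_frame,
)


def _one_patient_bundle(event_hours_before_end, values=None):
    """Single stay ending 2020-01-10T00:00:00 with one analyte."""
    end = pd.Timestamp("2020-01-10T00:00:00")
    times = [end - pd.Timedelta(hours=h) for h in event_hours_before_end]
    values = values or list(np.arange(len(times), dtype=float) + 1.0)
    labs = pd.DataFrame(
        {"patient_id": "p1", "analyte_code": "NA", "charttime": times,
         "value": values}
    )
    stays = pd.DataFrame(
        {"patient_id": ["p1"], "stay_start": [end - pd.Timedelta(hours=200)],
         "stay_end": [end], "specialty": ["icu"], "head_imaging": [0],
         "label": [0], "subtype": ["non_donor"], "died_in_icu": [0]}
    )
    panel = pd.DataFrame(
        {"analyte_code": ["NA"], "units": ["u"], "normal_low": [135.0],
         "normal_high": [145.0]}
    )
    return ds.CohortBundle(labs, stays, panel)


class TestBuildBlocks:
    @pytest.mark.parametrize(
        "hours_before_end, expected_block",
        [(3.0, 9), (0.0, 9), (8.0, 8), (71.9, 1)],
    )
    def test_block_boundaries(self, hours_before_end, expected_block):
        b = _one_patient_bundle([hours_before_end])
        t = ds.build_blocks(b)
        assert t.mask[0, 0, expected_block - 1] == MASK_OBSERVED

    def test_event_72h_old_discarded(self):
        t = ds.build_blocks(_one_patient_bundle([72.0]))
        assert (t.mask == MASK_UNSET).all()

    def test_event_after_anchor_discarded(self):
        b = _one_patient_bundle([10.0])
        anchors = default_anchors(b, truncation_hours=24.0)
        t = ds.build_blocks(b, anchors)
        assert (t.mask == MASK_UNSET).all()

    def test_last_value_in_block_wins(self):
        # both events fall in block 1; the later one (70 h old) is kept
        b = _one_patient_bundle([71.9, 70.0], values=[1.0, 2.0])
        t = ds.build_blocks(b)
        assert t.values[0, 0, 0] == 2.0
        assert t.mask[0, 0, 1:].sum() == 0


class TestImputation:
    def test_lvcf_carries_forward_only(self):
        b = _one_patient_bundle([60.0], values=[5.0])  # block 2
        t = ds.impute_lvcf(ds.build_blocks(b))
        assert t.mask[0, 0, 0] == MASK_UNSET
        assert t.mask[0, 0, 1] == MASK_OBSERVED
        assert (t.mask[0, 0, 2:] == MASK_LVCF).all()
        assert (t.values[0, 0, 2:] == 5.0).all()

    def test_observed_never_overwritten(self, small_cohort):
        bundle = ds.compute_lab_prevalence(ds.select_index_stays(small_cohort))
        bundle.panel = ds.filter_rare_labs(bundle.panel)
        t0 = ds.build_blocks(bundle)
        t1 = ds.impute_lvcf(t0)
        t2 = ds.impute_normal_gaussian(t1, bundle.panel,
                                       np.random.default_rng(0))
        obs = t0.mask == MASK_OBSERVED
        np.testing.assert_array_equal(t2.values[obs], t0.values[obs])
        assert (t2.mask != MASK_UNSET).all()
        assert np.isfinite(t2.values).all()

    def test_gaussian_sigma_matches_normal_range(self):
        # sodium range [135, 145] -> mu 140, sigma ~ 2.5511
        assert normal_range_sigma(135.0, 145.0) == pytest.approx(2.55102, abs=1e-4)

    def test_gaussian_calibration_95pct(self):
        b = _one_patient_bundle([200.0])  # nothing in window: all gaussian
        t = ds.impute_lvcf(ds.build_blocks(b))
        big = t.copy()
        reps = 100_000 // N_BLOCKS + 1
        big.values = np.tile(t.values, (reps, 1, 1))
        big.mask = np.tile(t.mask, (reps, 1, 1))
        big.patient_ids = np.array([f"p{i}" for i in range(reps)])
        out = ds.impute_normal_gaussian(big, b.panel, np.random.default_rng(7))
        draws = out.values[out.mask == MASK_GAUSSIAN]
        inside = ((draws >= 135.0) & (draws <= 145.0)).mean()
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_pipeline_deterministic(self, small_cohort):
        bundle = ds.compute_lab_prevalence(ds.select_index_stays(small_cohort))
        bundle.panel = ds.filter_rare_labs(bundle.panel)
        runs = []
        for _ in range(2):
            t = ds.impute_normal_gaussian(
                ds.impute_lvcf(ds.build_blocks(bundle)), bundle.panel,
                np.random.default_rng(123),
            )
            runs.append(t)
        np.testing.assert_array_equal(runs[0].values, runs[1].values)
        np.testing.assert_array_equal(runs[0].mask, runs[1].mask)


class TestPrevalenceFilter:
    def test_per_stay_counting(self):
        b = _one_patient_bundle([3.0, 5.0])  # two orders, one stay
        prev = ds.compute_lab_prevalence(b).panel["prevalence"]
        assert prev.iloc[0] == 1.0

    def test_rare_filter_strict_less_than(self):
        panel = pd.DataFrame(
            {"analyte_code": ["a", "b", "c"], "units": "u",
             "normal_low": 0.0, "normal_high": 1.0,
             "prevalence": [0.09, 0.10, 0.50]}
        )
        kept = ds.filter_rare_labs(panel, 0.10)
        assert list(kept["analyte_code"]) == ["b", "c"]
        kept2 = ds.filter_rare_labs(panel, 0.50)
        assert list(kept2["analyte_code"]) == ["c"]

    def test_threshold_zero_identity(self):
        panel = pd.DataFrame(
            {"analyte_code": ["a"], "units": "u", "normal_low": 0.0,
             "normal_high": 1.0, "prevalence": [0.01]}
        )
        assert len(ds.filter_rare_labs(panel, 0.0)) == 1

    def test_empty_survivors_error(self):
        panel = pd.DataFrame(
            {"analyte_code": ["a"], "units": "u", "normal_low": 0.0,
             "normal_high": 1.0, "prevalence": [0.05]}
        )
        with pytest.raises(ValueError, match="every analyte"):
            ds.filter_rare_labs(panel, 0.5)

    def test_simulator_rare_fraction_recovered(self, small_cohort):
        bundle = ds.compute_lab_prevalence(ds.select_index_stays(small_cohort))
        frac_rare = (bundle.panel["prevalence"] < 0.10).mean()
        assert abs(frac_rare - 0.25) <= 0.15


def test_standardization_fit_rows_only(small_cohort):
    bundle = ds.compute_lab_prevalence(ds.select_index_stays(small_cohort))
    bundle.panel = ds.filter_rare_labs(bundle.panel)
    t = ds.impute_normal_gaussian(
        ds.impute_lvcf(ds.build_blocks(bundle)), bundle.panel,
        np.random.default_rng(0),
    )
    rows = np.zeros(t.shape[0], bool)
    rows[: t.shape[0] // 2] = True
    std = Standardization.fit(t, rows)
    z = std.transform(t)
    np.testing.assert_allclose(z.values[rows].mean(axis=(0, 2)), 0.0,
                               atol=1e-6)
    np.testing.assert_allclose(z.values[rows].std(axis=(0, 2)), 1.0,
                               atol=1e-5)


def test_tensor_frame_roundtrip(small_cohort):
    bundle = ds.compute_lab_prevalence(ds.select_index_stays(small_cohort))
    bundle.panel = ds.filter_rare_labs(bundle.panel)
    t = ds.build_blocks(bundle)
    back = frame_to_tensor(tensor_to_frame(t), t.analytes)
    np.testing.assert_array_equal(back.values, t.values)
    np.testing.assert_array_equal(back.mask, t.mask)
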