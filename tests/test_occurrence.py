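"""Censoring bounds, survey summaries and distribution-family selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bprisk.occurrence import (
    DegenerateSampleError,
    OccurrenceRecord,
    apply_bounds,
    fit_distribution,
    load_survey_summary,
    read_occurrence_csv,
    summarize,
    write_occurrence_csv,
)


def rec(value=None, status="detected", lod=0.05, loq=0.29, cat="cereal", analyte="BP"):
    return OccurrenceRecord(
        food_category=cat, analyte=analyte, value=value, status=status, lod=lod, loq=loq
    )


class TestApplyBounds:
    def test_detected_unchanged_under_both_bounds(self):
        bounded = apply_bounds([rec(12.0)])
        assert bounded.lb_values[0] == bounded.ub_values[0] == 12.0

    def test_below_lod_substitutes_zero_and_lod(self):
        bounded = apply_bounds([rec(None, "lt_lod", lod=0.05)])
        assert bounded.lb_values[0] == 0.0
        assert bounded.ub_values[0] == 0.05

    def test_below_loq_substitutes_zero_and_loq(self):
        bounded = apply_bounds([rec(None, "lt_loq", loq=0.29)])
        assert bounded.lb_values[0] == 0.0
        assert bounded.ub_values[0] == 0.29

    def test_output_length_and_elementwise_order(self):
        records = [rec(5.0), rec(None, "lt_lod"), rec(None, "lt_loq"), rec(0.4)]
        bounded = apply_bounds(records)
        assert len(bounded.lb_values) == len(records)
        assert np.all(bounded.lb_values <= bounded.ub_values)

    def test_mixed_keys_rejected(self):
        with pytest.raises(ValueError):
            apply_bounds([rec(1.0, cat="a"), rec(1.0, cat="b")])

    def test_full_detection_makes_bounds_identical(self):
        records = [rec(v) for v in (1.0, 2.5, 7.0)]
        bounded = apply_bounds(records)
        assert np.array_equal(bounded.lb_values, bounded.ub_values)


class TestSummarize:
    def test_closed_form_two_values(self):
        s = summarize([rec(2.0), rec(8.0)])
        assert s.am == 5.0
        assert s.gm == pytest.approx(4.0)
        assert s.detection_rate == 100.0
        assert (s.min, s.max) == (2.0, 8.0)

    def test_detection_rate_ratio(self):
        records = [rec(1.0)] * 17 + [rec(None, "lt_loq")] * 3
        assert summarize(records).detection_rate == pytest.approx(85.0)

    def test_no_detections_gives_absent_statistics(self):
        s = summarize([rec(None, "lt_lod")] * 5)
        assert s.detection_rate == 0.0
        assert s.gm is None and s.am is None


class TestFitDistribution:
    def test_lognormal_sample_selects_lognormal(self):
        rng = np.random.default_rng(0)
        values = rng.lognormal(np.log(10), np.log(2), size=5000)
        assert fit_distribution(values).family == "lognormal"

    def test_normal_sample_selects_normal(self):
        rng = np.random.default_rng(0)
        values = rng.normal(100, 5, size=8000)
        assert fit_distribution(values).family == "normal"

    def test_selection_frequency_over_replicates(self):
        """Family selection is right in >95% of replicates from either truth."""
        hits_ln = hits_n = 0
        n_rep = 50
        for i in range(n_rep):
            rng = np.random.default_rng(1000 + i)
            if fit_distribution(rng.lognormal(np.log(10), np.log(2), 5000)).family == "lognormal":
                hits_ln += 1
            if fit_distribution(rng.normal(100, 5, 20_000)).family == "normal":
                hits_n += 1
        assert hits_ln / n_rep > 0.95
        assert hits_n / n_rep > 0.95

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            fit_distribution([3.0] * 20)

    def test_nonpositive_values_fall_back_to_normal_with_warning(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(5, 1, 100), [0.0]])
        with pytest.warns(UserWarning):
            spec = fit_distribution(values)
        assert spec.family == "normal"

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_distribution([1.0, 2.0, 3.0])


@settings(deadline=None, max_examples=50)
@given(
    detected=st.lists(st.floats(0.1, 1e4), min_size=1, max_size=20),
    censored=st.lists(st.sampled_from(["lt_lod", "lt_loq"]), max_size=20),
)
def test_bounding_monotonicity_property(detected, censored):
    """Every LB statistic is bounded by its UB counterpart."""
    records = [rec(v) for v in detected] + [rec(None, s) for s in censored]
    bounded = apply_bounds(records)
    assert np.all(bounded.lb_values <= bounded.ub_values)
    assert bounded.lb_values.mean() <= bounded.ub_values.mean()
    for q in (10, 50, 90, 97.5):
        assert np.percentile(bounded.lb_values, q) <= np.percentile(bounded.ub_values, q)


def test_csv_roundtrip(tmp_path):
    records = [rec(12.0), rec(None, "lt_lod"), rec(None, "lt_loq")]
    path = tmp_path / "occ.csv"
    write_occurrence_csv(records, path)
    header = path.read_text().splitlines()[0]
    assert header == "food_category,analyte,value_ng_per_g,status,lod_ng_per_g,loq_ng_per_g,packaging"
    assert read_occurrence_csv(path) == records


def test_packaged_survey_summary_shape():
    df = load_survey_summary()
    assert df["n"].groupby(df["food_category"]).first().sum() == 362
    assert set(df["analyte"]) == {"BP", "4-MBP", "4-OHBP", "M2BB", "PBZ"}
    assert (df.groupby("food_category")["detection_rate_pct"].max() == 100).all()
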