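"""Synthetic survey generator: determinism, censoring structure, recovery."""

import numpy as np
import pytest

from bprisk import generate_occurrence, generate_population
from bprisk.config import default_generator_config
from bprisk.occurrence import group_records, summarize

from conftest import single_pair_config


def test_full_detection_yields_no_censored_records():
    records = generate_occurrence(single_pair_config(detection_rate=1.0, n_samples=50))
    assert len(records) == 50
    assert all(r.status == "detected" for r in records)


def test_zero_detection_yields_all_censored_with_zero_lower_bound():
    from bprisk import apply_bounds

    records = generate_occurrence(single_pair_config(detection_rate=0.0, n_samples=50))
    assert len(records) == 50
    assert all(r.status in ("lt_lod", "lt_loq") for r in records)
    bounded = apply_bounds(records)
    assert np.all(bounded.lb_values == 0.0)


def test_geometric_mean_recovery_at_large_n():
    """Generated detected values recover the configured GM within 2%."""
    cfg = single_pair_config(
        detection_rate=1.0, gm=34.0, gsd=1.8, n_samples=10_000, seed=7, truncate_at_loq=False
    )
    records = generate_occurrence(cfg)
    values = np.array([r.value for r in records])
    gm = np.exp(np.mean(np.log(values)))
    assert gm == pytest.approx(34.0, rel=0.02)


def test_detection_rate_converges_binomially():
    rate = 0.85
    n = 10_000
    cfg = single_pair_config(detection_rate=rate, n_samples=n, seed=3)
    records = generate_occurrence(cfg)
    observed = sum(r.status == "detected" for r in records) / n
    # 4-sigma binomial tolerance
    tol = 4 * np.sqrt(rate * (1 - rate) / n)
    assert abs(observed - rate) < tol


def test_detected_values_truncated_at_loq():
    cfg = single_pair_config(detection_rate=1.0, gm=0.5, gsd=2.5, loq=0.29, lod=0.05, n_samples=500)
    records = generate_occurrence(cfg)
    assert all(r.value >= 0.29 for r in records)


def test_censored_split_between_lod_and_loq():
    cfg = single_pair_config(detection_rate=0.0, n_samples=2000, seed=11)
    records = generate_occurrence(cfg)
    frac_lod = sum(r.status == "lt_lod" for r in records) / len(records)
    assert frac_lod == pytest.approx(0.5, abs=0.05)


def test_seed_determinism_byte_identical():
    cfg = default_generator_config(seed=42)
    a = generate_occurrence(cfg)
    b = generate_occurrence(cfg)
    assert a == b


def test_different_seeds_differ():
    a = generate_occurrence(single_pair_config(seed=1))
    b = generate_occurrence(single_pair_config(seed=2))
    assert a != b


def test_default_config_covers_survey_structure(default_config):
    """Default survey: 8 categories, per-pair sample counts, all age groups."""
    assert len(default_config.food_categories) == 8
    records = generate_occurrence(default_config)
    grouped = group_records(records)
    for cat in default_config.food_categories:
        for analyte in default_config.analyte_specs[cat.name]:
            assert len(grouped[(cat.name, analyte)]) == cat.n_samples


def test_population_echoes_config(default_config):
    groups = generate_population(default_config)
    labels = {g.age_group for g in groups}
    assert labels == {"0-3", "3-6", "6-12", "12-16", "16-18", "19-65", ">65"}
    for g in groups:
        assert g.bw_spec.family == "normal"
        assert len(g.ir_specs) == 8
        assert all(spec.family == "lognormal" for spec in g.ir_specs.values())


def test_degenerate_body_weight_sd_zero():
    cfg = single_pair_config(bw_mean=10.0, bw_sd=0.0)
    (group,) = generate_population(cfg)
    rng = np.random.default_rng(0)
    bw = group.bw_spec.sample(rng, 100)
    assert np.all(bw == 10.0)


def test_generator_summary_roundtrip(default_config):
    """summarize(generate(...)) recovers configured detection rates."""
    records = generate_occurrence(default_config)
    grouped = group_records(records)
    spec = default_config.analyte_specs["cereal_I_rice_flour"]["4-MBP"]
    summary = summarize(grouped[("cereal_I_rice_flour", "4-MBP")])
    # n=59 samples: binomial noise is large, use a generous band
    assert summary.detection_rate == pytest.approx(100 * spec.detection_rate, abs=15)


def test_invalid_spec_rejected():
    with pytest.raises(Exception):
        single_pair_config(gsd=0.9)
    with pytest.raises(Exception):
        single_pair_config(lod=1.0, loq=0.5)
    with pytest.raises(Exception):
        single_pair_config(detection_rate=1.5)
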