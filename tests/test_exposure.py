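"""ADD arithmetic, Monte Carlo simulation and the exposure table."""

import numpy as np
import pytest
from scipy import stats

from bprisk import (
    AddDistribution,
    DistributionSpec,
    PopulationGroup,
    ScenarioSpec,
    add_point,
    assemble_exposure_table,
    simulate_add,
)


def degenerate_group(bw=10.0, categories=("cereal",), ir=100.0):
    return PopulationGroup(
        age_group="adult",
        bw_spec=DistributionSpec("normal", bw, 0.0),
        ir_specs={c: DistributionSpec("lognormal", np.log(ir), 0.0) for c in categories},
    )


class TestAddPoint:
    def test_sml_scale_arithmetic(self):
        # 600 ng/g is the 0.6 mg/kg migration limit expressed in ng/g
        assert add_point(600, 100, 1.0, 10) == pytest.approx(6.0e-3)

    def test_zero_concentration(self):
        assert add_point(0, 123, 0.5, 7) == 0.0

    def test_hand_arithmetic(self):
        assert add_point(34, 50, 1.0, 17) == pytest.approx(1.0e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            add_point(1, 1, 1.0, 0)
        with pytest.raises(ValueError):
            add_point(-1, 1, 1.0, 10)
        with pytest.raises(ValueError):
            add_point(1, 1, 1.5, 10)


class TestSimulateAdd:
    def test_degenerate_reduces_to_point_arithmetic(self):
        spec = ScenarioSpec(
            id=2, bound="UB", concentration_specs={"cereal": DistributionSpec("normal", 600.0, 0.0)}
        )
        dist = simulate_add(spec, degenerate_group(), "BP", n_iter=500, seed=0)
        assert np.allclose(dist.samples, 6.0e-3)
        assert dist.p50 == pytest.approx(6.0e-3)
        assert dist.p97_5 == pytest.approx(6.0e-3)

    def test_additivity_across_categories(self):
        one = ScenarioSpec(
            id=2, concentration_specs={"a": DistributionSpec("normal", 600.0, 0.0)}
        )
        two = ScenarioSpec(
            id=2,
            concentration_specs={
                "a": DistributionSpec("normal", 600.0, 0.0),
                "b": DistributionSpec("normal", 600.0, 0.0),
            },
        )
        d1 = simulate_add(one, degenerate_group(categories=("a",)), "BP", n_iter=100, seed=0)
        d2 = simulate_add(two, degenerate_group(categories=("a", "b")), "BP", n_iter=100, seed=0)
        assert np.allclose(d2.samples, 2 * d1.samples)

    def test_scale_equivariance_in_concentration(self):
        base = {"cereal": DistributionSpec("lognormal", np.log(30.0), 0.4)}
        scaled = {"cereal": DistributionSpec("lognormal", np.log(30.0 * 7), 0.4)}
        group = PopulationGroup(
            age_group="adult",
            bw_spec=DistributionSpec("normal", 60.0, 8.0),
            ir_specs={"cereal": DistributionSpec("lognormal", np.log(100.0), np.log(1.5))},
        )
        d1 = simulate_add(ScenarioSpec(id=2, concentration_specs=base), group, "BP", n_iter=2000, seed=5)
        d7 = simulate_add(ScenarioSpec(id=2, concentration_specs=scaled), group, "BP", n_iter=2000, seed=5)
        assert np.allclose(d7.samples, 7 * d1.samples, rtol=1e-12)

    def test_closed_form_lognormal_p975(self):
        """All-lognormal single category: P97.5 matches the analytic quantile.

        C*IR/BW is lognormal with mu = mu_c + mu_i - mu_b and
        sigma^2 = the sum of squared sigmas; the 97.5th percentile is
        exp(mu + 1.95996 sigma) * 1e-6.
        """
        mu_c, s_c = np.log(30.0), 0.5
        mu_i, s_i = np.log(100.0), 0.4
        mu_b, s_b = np.log(60.0), 0.2
        spec = ScenarioSpec(
            id=2, concentration_specs={"cereal": DistributionSpec("lognormal", mu_c, s_c)}
        )
        group = PopulationGroup(
            age_group="adult",
            bw_spec=DistributionSpec("lognormal", mu_b, s_b),
            ir_specs={"cereal": DistributionSpec("lognormal", mu_i, s_i)},
        )
        dist = simulate_add(spec, group, "BP", n_iter=100_000, seed=2)
        z = stats.norm.ppf(0.975)
        sigma = np.sqrt(s_c**2 + s_i**2 + s_b**2)
        analytic = np.exp(mu_c + mu_i - mu_b + z * sigma) * 1e-6
        assert dist.p97_5 == pytest.approx(analytic, rel=0.03)

    def test_seed_determinism(self):
        spec = ScenarioSpec(
            id=2, concentration_specs={"cereal": DistributionSpec("lognormal", np.log(30.0), 0.5)}
        )
        group = PopulationGroup(
            age_group="adult",
            bw_spec=DistributionSpec("normal", 60.0, 8.0),
            ir_specs={"cereal": DistributionSpec("lognormal", np.log(100.0), np.log(1.5))},
        )
        a = simulate_add(spec, group, "BP", n_iter=200, seed=9)
        b = simulate_add(spec, group, "BP", n_iter=200, seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_monte_carlo_stability_across_seeds(self):
        """P97.5 coefficient of variation across seeds < 5% at 10,000 iterations."""
        spec = ScenarioSpec(
            id=2, concentration_specs={"cereal": DistributionSpec("lognormal", np.log(30.0), 0.5)}
        )
        group = PopulationGroup(
            age_group="adult",
            bw_spec=DistributionSpec("normal", 60.0, 8.0),
            ir_specs={"cereal": DistributionSpec("lognormal", np.log(100.0), np.log(1.5))},
        )
        p975 = [
            simulate_add(spec, group, "BP", n_iter=10_000, seed=s).p97_5 for s in range(8)
        ]
        cv = np.std(p975) / np.mean(p975)
        assert cv < 0.05

    def test_missing_sml_is_configuration_error(self):
        spec = ScenarioSpec.scenario1()
        with pytest.raises(KeyError):
            simulate_add(spec, degenerate_group(), "2-OHBP", n_iter=10, seed=0)

    def test_bad_n_iter(self):
        with pytest.raises(ValueError):
            simulate_add(ScenarioSpec.scenario1(), degenerate_group(), "BP", n_iter=0)


class TestExposureTable:
    @staticmethod
    def fake(analyte, group, bound, p50=1e-5, p975=2e-5):
        return AddDistribution(
            analyte=analyte,
            age_group=group,
            scenario=2,
            bound=bound,
            samples=np.array([p50]),
            p50=p50,
            p97_5=p975,
            n_iterations=1,
            seed=0,
        )

    def test_cardinality(self):
        results = [
            self.fake(a, g, b)
            for a in ("BP", "4-MBP", "M2BB", "PBZ", "4-OHBP", "2-OHBP")
            for g in ("g1", "g2", "g3", "g4", "g5", "g6", "g7")
            for b in ("LB", "UB")
        ]
        table = assemble_exposure_table(results)
        assert len(table) == 84

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError):
            assemble_exposure_table([self.fake("BP", "g", "UB"), self.fake("BP", "g", "UB")])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assemble_exposure_table([])
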