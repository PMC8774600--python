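"""Synthetic survey generator.

Produces occurrence datasets and population consumption tables with the
statistical structure the exposure assessment assumes — per-analyte detection
rates with left-censoring against LOD/LOQ limits, lognormal concentration
bodies, lognormal intake rates and normal body weights — so the full
pipeline can run and be tested without access to any laboratory or national
consumption survey data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .config import GeneratorConfig
from .exposure import PopulationGroup
from .occurrence import DistributionSpec, OccurrenceRecord

POPULATION_COLUMNS = [
    "age_group",
    "bw_mean_kg",
    "bw_sd_kg",
    "food_category",
    "ir_gm_g_day",
    "ir_gsd",
]


def _truncated_lognormal(
    rng: np.random.Generator, mu: float, sigma: float, lower: float, n: int
) -> np.ndarray:
    """Draw lognormal(mu, sigma) left-truncated at ``lower`` by inverse CDF."""
    if n == 0:
        return np.empty(0)
    if sigma == 0:
        return np.full(n, np.exp(mu))
    lo = stats.norm.cdf((np.log(lower) - mu) / sigma) if lower > 0 else 0.0
    # guard against a truncation point far in the upper tail
    lo = min(lo, 1.0 - 1e-12)
    u = lo + (1.0 - lo) * rng.random(n)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def generate_occurrence(config: GeneratorConfig) -> list[OccurrenceRecord]:
    """Generate one synthetic occurrence survey.

    For each configured (category, analyte) pair, ``n_samples`` records are
    drawn: each is detected with probability ``detection_rate``; detected
    values follow the configured lognormal left-truncated at the LOQ (when
    ``truncate_at_loq``), and censored records are split between ``lt_lod``
    and ``lt_loq`` status per ``censored_lod_fraction``.  Identical configs
    (including the seed) produce identical output.
    """
    records: list[OccurrenceRecord] = []
    for category in config.food_categories:
        specs = config.analyte_specs.get(category.name, {})
        packaging = "synthetic-" + category.matrix_kind
        for analyte in sorted(specs):
            spec = specs[analyte]
            rng = substream(config.seed, "occurrence", category.name, analyte)
            n = category.n_samples
            detected_mask = rng.random(n) < spec.detection_rate
            n_det = int(detected_mask.sum())
            mu, sigma = np.log(spec.gm), np.log(spec.gsd)
            lower = spec.loq if config.truncate_at_loq else 0.0
            values = _truncated_lognormal(rng, mu, sigma, lower, n_det)
            censored_status = np.where(
                rng.random(n - n_det) < config.censored_lod_fraction, "lt_lod", "lt_loq"
            )
            det_iter = iter(values)
            cens_iter = iter(censored_status)
            for is_det in detected_mask:
                if is_det:
                    records.append(
                        OccurrenceRecord(
                            food_category=category.name,
                            analyte=analyte,
                            value=float(next(det_iter)),
                            status="detected",
                            lod=spec.lod,
                            loq=spec.loq,
                            packaging=packaging,
                        )
                    )
                else:
                    records.append(
                        OccurrenceRecord(
                            food_category=category.name,
                            analyte=analyte,
                            value=None,
                            status=str(next(cens_iter)),
                            lod=spec.lod,
                            loq=spec.loq,
                            packaging=packaging,
                        )
                    )
    return records


def generate_population(config: GeneratorConfig) -> list[PopulationGroup]:
    """Materialize the configured age groups as PopulationGroup objects.

    Purely deterministic: body weight becomes a normal spec and each
    intake rate a lognormal spec, echoing the configuration.
    """
    groups = []
    for name, pop in config.population_specs.items():
        bw = DistributionSpec("normal", pop.bw_mean, pop.bw_sd)
        ir = {
            cat: DistributionSpec.lognormal_from_gm(spec.gm, spec.gsd)
            for cat, spec in pop.ir.items()
        }
        groups.append(PopulationGroup(age_group=name, bw_spec=bw, ir_specs=ir))
    return groups


# ---------------------------------------------------------------------------
# population table I/O


def population_to_frame(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for group, pop in config.population_specs.items():
        for cat, spec in pop.ir.items():
            rows.append(
                {
                    "age_group": group,
                    "bw_mean_kg": pop.bw_mean,
                    "bw_sd_kg": pop.bw_sd,
                    "food_category": cat,
                    "ir_gm_g_day": spec.gm,
                    "ir_gsd": spec.gsd,
                }
            )
    return pd.DataFrame(rows, columns=POPULATION_COLUMNS)


def write_population_csv(config: GeneratorConfig, path) -> None:
    population_to_frame(config).to_csv(path, index=False)


def read_population_csv(path) -> list[PopulationGroup]:
    """Read a population table into PopulationGroup objects."""
    df = pd.read_csv(path)
    missing = set(POPULATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"population CSV missing columns: {sorted(missing)}")
    groups = []
    for name, sub in df.groupby("age_group", sort=False):
        bw = DistributionSpec("normal", float(sub["bw_mean_kg"].iloc[0]), float(sub["bw_sd_kg"].iloc[0]))
        ir = {
            str(row.food_category): DistributionSpec.lognormal_from_gm(
                float(row.ir_gm_g_day), float(row.ir_gsd)
            )
            for row in sub.itertuples(index=False)
        }
        groups.append(PopulationGroup(age_group=str(name), bw_spec=bw, ir_specs=ir))
    return groups
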