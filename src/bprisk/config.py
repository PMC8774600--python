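"""Configuration models for the synthetic survey generator and pipeline runs.

The default generator configuration is derived from the packaged occurrence
summary table so that synthetic surveys reproduce the detection rates, sample
sizes and concentration magnitudes of the real survey, category by category.
Population intake-rate and body-weight parameters are synthetic: the national
consumption survey appendix underlying the original analysis is not public,
so defaults are plausible round numbers chosen to put exposures on the scale
the survey-based assessment reports (see docs/methods.md).
"""

from __future__ import annotations

import math
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

DEFAULT_AGE_GROUPS = ("0-3", "3-6", "6-12", "12-16", "16-18", "19-65", ">65")

#: Fallback geometric standard deviation for rows whose printed GM cell is
#: unusable (GM >= mean, or mean-only rows); typical for food-contaminant data.
DEFAULT_GSD = 1.5

#: LOD is taken as 0.3 x LOQ (signal-to-noise 3 vs 10 definition of the limits).
LOD_TO_LOQ = 0.3


class FoodCategory(BaseModel):
    """A surveyed food category; liquids are treated at density 1 g/mL."""

    name: str
    matrix_kind: Literal["solid", "liquid"] = "solid"
    n_samples: int = Field(default=50, ge=1)


class AnalyteSpec(BaseModel):
    """Concentration model for one analyte in one food category.

    Detected values follow a lognormal body (geometric mean ``gm`` ng/g,
    geometric SD ``gsd``) left-truncated at the LOQ so that generated data
    are internally consistent with their censoring flags.
    """

    detection_rate: float = Field(ge=0.0, le=1.0)
    gm: float = Field(gt=0.0)
    gsd: float = Field(gt=1.0)
    lod: float = Field(gt=0.0)
    loq: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _limits_ordered(self) -> "AnalyteSpec":
        if self.lod > self.loq:
            raise ValueError(f"lod ({self.lod}) must not exceed loq ({self.loq})")
        return self


class IntakeSpec(BaseModel):
    """Lognormal daily intake rate of one food category, g/day."""

    gm: float = Field(gt=0.0)
    gsd: float = Field(gt=1.0)


class PopulationSpec(BaseModel):
    """Normal body weight (kg) and per-category intake rates for an age group."""

    bw_mean: float = Field(gt=0.0)
    bw_sd: float = Field(ge=0.0)
    ir: dict[str, IntakeSpec]


class GeneratorConfig(BaseModel):
    """Full specification of a synthetic occurrence + consumption survey."""

    seed: int = 0
    food_categories: list[FoodCategory]
    analyte_specs: dict[str, dict[str, AnalyteSpec]]  # category -> analyte -> spec
    population_specs: dict[str, PopulationSpec]  # age group -> spec
    #: fraction of censored records labelled ``lt_lod`` (the rest ``lt_loq``)
    censored_lod_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    #: left-truncate detected draws at the LOQ
    truncate_at_loq: bool = True

    @field_validator("food_categories")
    @classmethod
    def _unique_names(cls, v: list[FoodCategory]) -> list[FoodCategory]:
        names = [c.name for c in v]
        if len(set(names)) != len(names):
            raise ValueError("duplicate food category names")
        return v

    @model_validator(mode="after")
    def _categories_known(self) -> "GeneratorConfig":
        known = {c.name for c in self.food_categories}
        bad = set(self.analyte_specs) - known
        if bad:
            raise ValueError(f"analyte_specs reference unknown categories: {sorted(bad)}")
        for group, pop in self.population_specs.items():
            bad = set(pop.ir) - known
            if bad:
                raise ValueError(f"population {group!r} references unknown categories: {sorted(bad)}")
        return self

    def category(self, name: str) -> FoodCategory:
        for cat in self.food_categories:
            if cat.name == name:
                return cat
        raise KeyError(name)

    # -- YAML round-trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))


def gsd_from_am_gm(am: float, gm: float) -> float:
    """Geometric SD implied by arithmetic and geometric means of a lognormal.

    For LN(mu, sigma): AM = GM * exp(sigma^2 / 2), hence
    sigma = sqrt(2 ln(AM/GM)).  Only meaningful when AM > GM.
    """
    if am <= gm:
        raise ValueError("requires am > gm")
    return math.exp(math.sqrt(2.0 * math.log(am / gm)))


_LIQUID_CATEGORIES = {
    "juice_fresh_100",
    "juice_reconstituted_100",
    "juice_10pct_plus",
    "milk_full_fat",
    "milk_low_fat",
}

# Synthetic body-weight parameters (normal, kg) per age group.
_BW_DEFAULTS = {
    "0-3": (12.5, 1.8),
    "3-6": (18.0, 2.5),
    "6-12": (30.0, 5.0),
    "12-16": (48.0, 7.0),
    "16-18": (57.0, 8.0),
    "19-65": (64.0, 10.0),
    ">65": (60.0, 9.0),
}

# Synthetic intake-rate geometric means (g/day) per age group, in category
# order: cereal I, cereal II, cereal III, fresh juice, reconstituted juice,
# 10%+ juice, full-fat milk, low-fat milk.  A common GSD of 1.5 is used.
_IR_GM_DEFAULTS = {
    "0-3": (6, 6, 6, 10, 20, 12, 50, 15),
    "3-6": (8, 9, 8, 12, 25, 15, 55, 18),
    "6-12": (12, 14, 12, 15, 30, 20, 55, 22),
    "12-16": (15, 18, 15, 18, 35, 25, 55, 25),
    "16-18": (16, 19, 16, 18, 38, 26, 50, 25),
    "19-65": (15, 18, 15, 20, 45, 30, 60, 30),
    ">65": (14, 16, 13, 15, 35, 22, 50, 28),
}
_IR_GSD_DEFAULT = 1.5

# 2-OHBP was assayed but detected too rarely to appear in the survey summary
# table; these synthetic specs give it a sparse presence in liquid categories
# so the TTC screening path is exercised end to end.
_SYNTHETIC_2OHBP = {
    "juice_reconstituted_100": dict(detection_rate=0.05, gm=0.3, gsd=1.8, lod=0.15, loq=0.5),
    "juice_10pct_plus": dict(detection_rate=0.05, gm=0.3, gsd=1.8, lod=0.15, loq=0.5),
    "milk_full_fat": dict(detection_rate=0.08, gm=0.4, gsd=1.8, lod=0.15, loq=0.5),
    "milk_low_fat": dict(detection_rate=0.08, gm=0.4, gsd=1.8, lod=0.15, loq=0.5),
}


def _analyte_spec_from_summary(row) -> AnalyteSpec:
    """Derive generator parameters from one survey-summary row.

    When the printed GM is consistent with a right-skewed lognormal
    (GM < mean), the GSD is recovered from the AM/GM ratio; otherwise the GM
    cell is treated as unreliable and the lognormal is re-anchored on the
    arithmetic mean with a default GSD.
    """
    am, gm = float(row.mean_ng_g), float(row.gm_ng_g)
    if gm < am:
        gsd = min(max(gsd_from_am_gm(am, gm), 1.2), 4.0)
    else:
        gsd = DEFAULT_GSD
        gm = am / math.exp(0.5 * math.log(DEFAULT_GSD) ** 2)
    if bool(row.min_is_censored):
        loq = float(row.min_ng_g)
    else:
        # fully-quantified rows report a measured minimum; place the LOQ below it
        loq = float(row.min_ng_g) / 2.0
    return AnalyteSpec(
        detection_rate=float(row.detection_rate_pct) / 100.0,
        gm=gm,
        gsd=gsd,
        lod=loq * LOD_TO_LOQ,
        loq=loq,
    )


def default_generator_config(seed: int = 0) -> GeneratorConfig:
    """Build the default synthetic-survey configuration.

    Occurrence parameters come from the packaged survey summary; population
    parameters are the synthetic defaults documented above.
    """
    from .occurrence import load_survey_summary

    summary = load_survey_summary()
    cat_names = list(dict.fromkeys(summary["food_category"]))
    n_by_cat = summary.groupby("food_category")["n"].first().to_dict()
    categories = [
        FoodCategory(
            name=name,
            matrix_kind="liquid" if name in _LIQUID_CATEGORIES else "solid",
            n_samples=int(n_by_cat[name]),
        )
        for name in cat_names
    ]
    analyte_specs: dict[str, dict[str, AnalyteSpec]] = {name: {} for name in cat_names}
    for row in summary.itertuples(index=False):
        analyte_specs[row.food_category][row.analyte] = _analyte_spec_from_summary(row)
    for cat, kwargs in _SYNTHETIC_2OHBP.items():
        analyte_specs[cat]["2-OHBP"] = AnalyteSpec(**kwargs)

    population_specs = {}
    for group in DEFAULT_AGE_GROUPS:
        bw_mean, bw_sd = _BW_DEFAULTS[group]
        ir = {
            cat: IntakeSpec(gm=float(gm), gsd=_IR_GSD_DEFAULT)
            for cat, gm in zip(cat_names, _IR_GM_DEFAULTS[group])
        }
        population_specs[group] = PopulationSpec(bw_mean=bw_mean, bw_sd=bw_sd, ir=ir)

    return GeneratorConfig(
        seed=seed,
        food_categories=categories,
        analyte_specs=analyte_specs,
        population_specs=population_specs,
    )
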