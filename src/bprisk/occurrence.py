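"""Concentration (occurrence) data: records, censoring bounds, summaries, fits.

Survey measurements of photoinitiator residues in foods are left-censored:
a sample is either quantified (``detected``), below the limit of
quantification (``lt_loq``) or below the limit of detection (``lt_lod``).
Censored values are handled by substitution: the lower-bound (LB) convention
replaces them with zero, the upper-bound (UB) convention with the relevant
limit.  Detected values are identical under both bounds, so any statistic of
the LB sample is less than or equal to its UB counterpart.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ANALYTES = ("BP", "2-OHBP", "4-OHBP", "4-MBP", "M2BB", "PBZ")

Status = Literal["detected", "lt_lod", "lt_loq"]
Bound = Literal["LB", "UB"]

OCCURRENCE_COLUMNS = [
    "food_category",
    "analyte",
    "value_ng_per_g",
    "status",
    "lod_ng_per_g",
    "loq_ng_per_g",
    "packaging",
]


class DegenerateSampleError(ValueError):
    """Raised when a zero-variance sample cannot support a distribution fit."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One concentration measurement with its censoring status.

    ``value`` is in ng/g (liquids are treated at density 1 g/mL, so ng/mL is
    numerically identical).  A censored record carries no value.
    """

    food_category: str
    analyte: str
    value: float | None
    status: Status
    lod: float
    loq: float
    packaging: str = ""

    def __post_init__(self) -> None:
        if self.status == "detected":
            if self.value is None or self.value <= 0:
                raise ValueError("detected record requires a positive value")
        elif self.status in ("lt_lod", "lt_loq"):
            if self.value is not None:
                raise ValueError("censored record must not carry a value")
        else:
            raise ValueError(f"unknown status {self.status!r}")
        if self.lod > self.loq:
            raise ValueError("LOD must not exceed LOQ")


@dataclass
class BoundedSample:
    """LB and UB substituted values for one (category, analyte) sample."""

    food_category: str
    analyte: str
    lb_values: np.ndarray
    ub_values: np.ndarray

    def values(self, bound: Bound) -> np.ndarray:
        return self.lb_values if bound == "LB" else self.ub_values


@dataclass
class OccurrenceSummary:
    """Survey-table style summary of one (category, analyte) sample.

    ``detection_rate`` is a percentage; min/max/am/sd/gm are computed over
    detected values only and are ``None`` when nothing was detected (the
    geometric mean of lower-bound zeros is undefined).
    """

    n: int
    detection_rate: float
    min: float | None = None
    max: float | None = None
    am: float | None = None
    sd: float | None = None
    gm: float | None = None


@dataclass
class DistributionSpec:
    """A parametric family with its parameters (and KS fit diagnostics).

    normal: param1 = mean, param2 = standard deviation (natural scale).
    lognormal: param1 = mean of log values, param2 = sd of log values.
    A ``param2`` of zero denotes a degenerate (point-mass) specification.
    """

    family: Literal["normal", "lognormal"]
    param1: float
    param2: float
    ks_statistic: float | None = None
    ks_pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.param2 < 0:
            raise ValueError("scale parameter must be nonnegative")

    @classmethod
    def lognormal_from_gm(cls, gm: float, gsd: float) -> "DistributionSpec":
        if gm <= 0 or gsd < 1:
            raise ValueError("lognormal requires gm > 0 and gsd >= 1")
        return cls("lognormal", math.log(gm), math.log(gsd))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "normal":
            return rng.normal(self.param1, self.param2, size=n)
        return rng.lognormal(self.param1, self.param2, size=n)

    def ppf(self, q: float) -> float:
        if self.param2 == 0:
            return self.param1 if self.family == "normal" else math.exp(self.param1)
        if self.family == "normal":
            return float(stats.norm.ppf(q, self.param1, self.param2))
        return float(math.exp(stats.norm.ppf(q, self.param1, self.param2)))

    def mean(self) -> float:
        if self.family == "normal":
            return self.param1
        return math.exp(self.param1 + 0.5 * self.param2**2)


def _check_single_key(records: Sequence[OccurrenceRecord]) -> tuple[str, str]:
    keys = {(r.food_category, r.analyte) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records must share one (category, analyte), got {sorted(keys)}")
    return keys.pop()


def apply_bounds(records: Sequence[OccurrenceRecord], bound: Bound | None = None) -> BoundedSample:
    """Substitute censored values under the LB/UB conventions.

    Detected values pass through unchanged; ``lt_lod`` becomes 0 (LB) or the
    LOD (UB); ``lt_loq`` becomes 0 (LB) or the LOQ (UB).  Both bounds are
    always computed; ``bound`` is accepted for call-site symmetry but does
    not change the returned object.
    """
    if not records:
        raise ValueError("empty record list")
    category, analyte = _check_single_key(records)
    lb = np.empty(len(records))
    ub = np.empty(len(records))
    for i, rec in enumerate(records):
        if rec.status == "detected":
            lb[i] = ub[i] = rec.value  # type: ignore[assignment]
        elif rec.status == "lt_lod":
            lb[i], ub[i] = 0.0, rec.lod
        else:
            lb[i], ub[i] = 0.0, rec.loq
    return BoundedSample(category, analyte, lb, ub)


def summarize(records: Sequence[OccurrenceRecord]) -> OccurrenceSummary:
    """Compute detection rate and detected-value statistics for one sample."""
    if not records:
        raise ValueError("empty record list")
    _check_single_key(records)
    detected = np.array([r.value for r in records if r.status == "detected"], dtype=float)
    n = len(records)
    rate = 100.0 * detected.size / n
    if detected.size == 0:
        return OccurrenceSummary(n=n, detection_rate=0.0)
    return OccurrenceSummary(
        n=n,
        detection_rate=rate,
        min=float(detected.min()),
        max=float(detected.max()),
        am=float(detected.mean()),
        sd=float(detected.std(ddof=1)) if detected.size > 1 else 0.0,
        gm=float(np.exp(np.mean(np.log(detected)))),
    )


def fit_distribution(values: Sequence[float]) -> DistributionSpec:
    """Select normal vs lognormal by Kolmogorov-Smirnov p-value.

    Both families are fitted by maximum likelihood and the family with the
    larger KS p-value (against its own fitted parameters) is returned, ties
    broken toward lognormal, the conventional family for concentration data.
    The KS p-values are a selection heuristic, not a formal goodness-of-fit
    test (no correction for estimated parameters is applied).  Nonpositive
    values rule out the lognormal candidate; the normal fit is returned with
    a warning in that case.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 8:
        raise ValueError("need at least 8 values to fit a distribution")
    if np.ptp(arr) == 0:
        raise DegenerateSampleError("constant-value sample has no fittable spread")
    mean, sd = float(arr.mean()), float(arr.std(ddof=0))
    ks_norm = stats.kstest(arr, "norm", args=(mean, sd))
    normal_spec = DistributionSpec(
        "normal", mean, sd, ks_statistic=float(ks_norm.statistic), ks_pvalue=float(ks_norm.pvalue)
    )
    if np.any(arr <= 0):
        warnings.warn(
            "nonpositive values: lognormal candidate skipped, normal fit returned",
            stacklevel=2,
        )
        return normal_spec
    logs = np.log(arr)
    mu, sigma = float(logs.mean()), float(logs.std(ddof=0))
    ks_lnorm = stats.kstest(arr, "lognorm", args=(sigma, 0.0, math.exp(mu)))
    lognormal_spec = DistributionSpec(
        "lognormal", mu, sigma, ks_statistic=float(ks_lnorm.statistic), ks_pvalue=float(ks_lnorm.pvalue)
    )
    # tie broken toward lognormal
    if ks_norm.pvalue > ks_lnorm.pvalue:
        return normal_spec
    return lognormal_spec


# ---------------------------------------------------------------------------
# I/O


def records_to_frame(records: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    rows = [
        {
            "food_category": r.food_category,
            "analyte": r.analyte,
            "value_ng_per_g": r.value,
            "status": r.status,
            "lod_ng_per_g": r.lod,
            "loq_ng_per_g": r.loq,
            "packaging": r.packaging,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[OccurrenceRecord]:
    records = []
    for row in df.itertuples(index=False):
        value = row.value_ng_per_g
        if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
            value = None
        else:
            value = float(value)
        records.append(
            OccurrenceRecord(
                food_category=row.food_category,
                analyte=row.analyte,
                value=value,
                status=row.status,
                lod=float(row.lod_ng_per_g),
                loq=float(row.loq_ng_per_g),
                packaging="" if pd.isna(row.packaging) else str(row.packaging),
            )
        )
    return records


def write_occurrence_csv(records: Iterable[OccurrenceRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_occurrence_csv(path) -> list[OccurrenceRecord]:
    df = pd.read_csv(path, dtype={"packaging": str})
    missing = set(OCCURRENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    return frame_to_records(df)


def group_records(
    records: Iterable[OccurrenceRecord],
) -> dict[tuple[str, str], list[OccurrenceRecord]]:
    """Group records by (food_category, analyte)."""
    grouped: dict[tuple[str, str], list[OccurrenceRecord]] = {}
    for rec in records:
        grouped.setdefault((rec.food_category, rec.analyte), []).append(rec)
    return grouped


def load_survey_summary() -> pd.DataFrame:
    """Load the packaged occurrence summary table (survey of 362 samples).

    One row per (food category, analyte) with sample size, detection rate
    (percent), and detected-value min/max/mean/SD/GM in ng/g.  ``min_is_censored``
    flags rows whose reported minimum is a quantification limit rather than a
    measured value.  A handful of GM cells are internally inconsistent with
    their own row (GM above the mean or the maximum); they are transcribed
    as printed but never used to parameterize anything (see the generator's
    derivation rules in :mod:`bprisk.config`).
    """
    with resources.files("bprisk.data").joinpath("occurrence_summary.csv").open() as fh:
        return pd.read_csv(fh)
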