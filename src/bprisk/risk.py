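"""Risk characterization: MOE, cumulative MOE_T, RISK21 cells, TTC screening.

The margin of exposure is MOE = POD / ADD; values at or above the target MOE
(typically 100, covering inter- and intra-species uncertainty) are considered
protective.  Chemicals sharing a critical endpoint are combined into a
cumulative margin as the reciprocal of the sum of reciprocals,

    MOE_T = 1 / (1/MOE_1 + ... + 1/MOE_k),

which is bounded above by the smallest member MOE.  The RISK21 matrix
juxtaposes an exposure band (P50..P97.5 ADD) against a toxicity band
(POD range) to classify concern; TTC screening compares an exposure with a
structure-class threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

#: Analytes combined into the cumulative margin (shared kidney endpoint).
MOET_MEMBERS = ("BP", "4-MBP", "M2BB")

#: Cumulative-margin target: the most stringent member target (4-MBP's 200).
MOET_TARGET = 200.0


@dataclass
class MoeResult:
    analyte: str
    age_group: str
    scenario: int
    bound: str
    percentile: Literal["P50", "P97.5"]
    moe: float
    target_moe: float
    verdict: Literal["acceptable", "concern"] = field(init=False)
    pod_value: float = 0.0
    pod_type: str = ""
    endpoint_class: str = ""
    infinite: bool = False

    def __post_init__(self) -> None:
        self.verdict = "acceptable" if self.moe >= self.target_moe else "concern"


@dataclass
class MoetResult:
    age_group: str
    scenario: int
    bound: str
    percentile: str
    members: tuple[str, ...]
    moet: float
    target: float
    verdict: Literal["acceptable", "concern"] = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = "acceptable" if self.moet >= self.target else "concern"


@dataclass
class Risk21Cell:
    analyte: str
    age_group: str
    exposure_low: float  # P50 ADD, mg/kg bw/day
    exposure_high: float  # P97.5 ADD
    tox_low: float  # lower edge of the POD band
    tox_high: float
    classification: Literal["low", "moderate", "high"] = field(init=False)
    target_moe: float = 100.0

    def __post_init__(self) -> None:
        if self.exposure_low > self.exposure_high or self.tox_low > self.tox_high:
            raise ValueError("inverted exposure or toxicity band")
        if self.exposure_low >= self.tox_low:
            self.classification = "high"
        elif self.exposure_high * self.target_moe <= self.tox_low:
            self.classification = "low"
        else:
            self.classification = "moderate"


@dataclass
class TtcVerdict:
    analyte: str
    age_group: str
    exposure: float  # mg/kg bw/day
    threshold: float  # mg/kg bw/day
    verdict: Literal["below_threshold", "exceeds_threshold"] = field(init=False)

    def __post_init__(self) -> None:
        # strict comparison: exposure must be below the threshold
        self.verdict = "below_threshold" if self.exposure < self.threshold else "exceeds_threshold"


def compute_moe(pod: float, add: float) -> float:
    """Margin of exposure POD/ADD; an ADD of zero yields +inf (no concern)."""
    if pod <= 0:
        raise ValueError("POD must be positive")
    if add < 0:
        raise ValueError("ADD must be nonnegative")
    if add == 0:
        return math.inf
    return pod / add


def combine_moet(moes: Mapping[str, float]) -> float:
    """Cumulative margin: reciprocal of the sum of member reciprocals."""
    if not moes:
        raise ValueError("MOE_T requires at least one member")
    if any(m <= 0 for m in moes.values()):
        raise ValueError("all member MOEs must be positive")
    if len(moes) == 1:  # single member: identity, no reciprocal round-trip
        return float(next(iter(moes.values())))
    recip = sum(1.0 / m for m in moes.values())
    if recip == 0.0:  # all members infinite
        return math.inf
    return 1.0 / recip


def risk21_classify(
    analyte: str,
    age_group: str,
    exposure_low: float,
    exposure_high: float,
    tox_low: float,
    tox_high: float,
    target_moe: float = 100.0,
) -> Risk21Cell:
    """Place one analyte x age group in the RISK21 matrix.

    Concern is low when even the high exposure times the target MOE stays at
    or below the toxicity band (the target-MOE margin is met), high when the
    low exposure already reaches the toxicity band, moderate in between.
    """
    return Risk21Cell(
        analyte=analyte,
        age_group=age_group,
        exposure_low=exposure_low,
        exposure_high=exposure_high,
        tox_low=tox_low,
        tox_high=tox_high,
        target_moe=target_moe,
    )


def ttc_screen(analyte: str, age_group: str, add: float, threshold: float) -> TtcVerdict:
    """Screen an exposure against a TTC threshold (both mg/kg bw/day)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return TtcVerdict(analyte=analyte, age_group=age_group, exposure=add, threshold=threshold)
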