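"""Hazard registry: points of departure, guidance values and TTC rules.

The registry ships as a validated YAML document (``data/hazard_registry.yaml``)
with one block per analyte.  Analytes with animal toxicity data carry one or
more :class:`HazardProfile` entries — a point of departure (TDI, BMDL10 or
NOAEL, mg/kg bw/day) with its critical endpoint and target margin of
exposure — of which exactly one is marked primary.  Analytes without usable
toxicity data are flagged ``ttc_only`` with a Cramer structural class and are
screened against the threshold of toxicological concern (TTC): fixed
exposure thresholds of 1800 / 540 / 90 ug/person/day for Cramer classes
I / II / III.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal

import yaml
from pydantic import BaseModel, Field, model_validator


class HazardProfile(BaseModel):
    """One point of departure with its endpoint and MOE target."""

    analyte: str = ""
    pod_type: Literal["TDI", "BMDL10", "NOAEL"]
    pod_value: float = Field(gt=0.0)  # mg/kg bw/day
    endpoint: str
    endpoint_class: Literal["noncarcinogen", "carcinogen"]
    target_moe: float = Field(ge=1.0)
    source: str = ""
    primary: bool = False


class TTCRule(BaseModel):
    """Exposure threshold for one Cramer structural class."""

    cramer_class: Literal["I", "II", "III"]
    threshold_person: float = Field(gt=0.0)  # ug/person/day
    default_bw: float = Field(gt=0.0, default=60.0)  # kg


@dataclass
class AnalyteHazard:
    """All hazard information for one analyte."""

    analyte: str
    profiles: list[HazardProfile]
    ttc_only: bool = False
    cramer_class: str | None = None
    metadata: dict | None = None

    @property
    def primary(self) -> HazardProfile | None:
        for p in self.profiles:
            if p.primary:
                return p
        return None


class HazardRegistry(dict):
    """Mapping analyte -> AnalyteHazard, plus the TTC rule table."""

    def __init__(self, entries: dict[str, AnalyteHazard], ttc_rules: dict[str, TTCRule]):
        super().__init__(entries)
        self.ttc_rules = ttc_rules

    def ttc_rule(self, cramer_class: str, default_bw: float | None = None) -> TTCRule:
        rule = self.ttc_rules[cramer_class]
        if default_bw is not None:
            rule = rule.model_copy(update={"default_bw": default_bw})
        return rule

    def to_dict(self) -> dict:
        out: dict = {"analytes": {}, "ttc": {}}
        for name, entry in self.items():
            block: dict = {}
            if entry.profiles:
                block["profiles"] = [
                    p.model_dump(exclude={"analyte"}, exclude_defaults=False)
                    for p in entry.profiles
                ]
            if entry.ttc_only:
                block["ttc_only"] = True
                block["cramer_class"] = entry.cramer_class
            if entry.metadata:
                block["metadata"] = entry.metadata
            out["analytes"][name] = block
        any_rule = next(iter(self.ttc_rules.values()))
        out["ttc"] = {
            "default_bw_kg": any_rule.default_bw,
            "thresholds_ug_person_day": {
                cls: rule.threshold_person for cls, rule in self.ttc_rules.items()
            },
        }
        return out


class RegistryError(ValueError):
    """Raised when the registry document violates its schema."""


def _parse_registry(doc: dict) -> HazardRegistry:
    errors: list[str] = []
    entries: dict[str, AnalyteHazard] = {}
    for analyte, block in (doc.get("analytes") or {}).items():
        profiles = []
        for raw in block.get("profiles", []) or []:
            try:
                profiles.append(HazardProfile(analyte=analyte, **raw))
            except Exception as exc:  # collect all schema violations
                errors.append(f"{analyte}: {exc}")
        ttc_only = bool(block.get("ttc_only", False))
        if profiles and sum(p.primary for p in profiles) != 1:
            errors.append(f"{analyte}: exactly one profile must be primary")
        if not profiles and not ttc_only:
            errors.append(f"{analyte}: needs profiles or ttc_only")
        entries[analyte] = AnalyteHazard(
            analyte=analyte,
            profiles=profiles,
            ttc_only=ttc_only,
            cramer_class=block.get("cramer_class"),
            metadata=block.get("metadata"),
        )
    ttc_block = doc.get("ttc") or {}
    default_bw = float(ttc_block.get("default_bw_kg", 60.0))
    thresholds = ttc_block.get("thresholds_ug_person_day") or {}
    ttc_rules = {}
    for cls, value in thresholds.items():
        try:
            ttc_rules[cls] = TTCRule(cramer_class=cls, threshold_person=float(value), default_bw=default_bw)
        except Exception as exc:
            errors.append(f"ttc {cls}: {exc}")
    if sorted(ttc_rules) != ["I", "II", "III"]:
        errors.append("ttc thresholds must cover Cramer classes I, II, III")
    if errors:
        raise RegistryError("invalid hazard registry:\n  " + "\n  ".join(errors))
    return HazardRegistry(entries, ttc_rules)


def load_registry(path=None) -> HazardRegistry:
    """Load and validate the hazard registry (packaged file by default)."""
    if path is None:
        with resources.files("bprisk.data").joinpath("hazard_registry.yaml").open() as fh:
            doc = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    return _parse_registry(doc)


def ttc_threshold_per_bw(rule: TTCRule) -> tuple[float, float]:
    """Body-weight-normalized TTC threshold.

    Returns ``(ug/kg bw/day, mg/kg bw/day)`` for the rule's default body
    weight; e.g. Cramer class III at 60 kg gives (1.5, 0.0015).
    """
    if rule.default_bw <= 0:
        raise ValueError("body weight must be positive")
    ug_kg_day = rule.threshold_person / rule.default_bw
    return ug_kg_day, ug_kg_day / 1000.0
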