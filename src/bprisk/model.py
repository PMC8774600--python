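"""Model/Results interface for the cumulative dietary risk assessment.

:class:`DietaryRiskModel` bundles the three data inputs — an occurrence
survey, a population table of body weights and intake rates, and the hazard
registry — and :meth:`DietaryRiskModel.fit` runs the full probabilistic
assessment for one exposure scenario: Monte Carlo average-daily-dose
simulation per analyte and age group under the censoring bounds, margin of
exposure (MOE) and cumulative MOE_T characterization, RISK21 banding, TTC
screening for data-poor analytes, and contribution-to-variance sensitivity
analysis.  The returned :class:`RiskAssessmentResults` holds everything as
tidy tables with ``summary()``, ``save()`` and plotting helpers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .config import GeneratorConfig, default_generator_config
from .exposure import (
    SML_MG_KG,
    AddDistribution,
    PopulationGroup,
    ScenarioSpec,
    assemble_exposure_table,
    simulate_add,
)
from .hazard import HazardRegistry, load_registry, ttc_threshold_per_bw
from .occurrence import ANALYTES, OccurrenceRecord, group_records, read_occurrence_csv
from .risk import (
    MOET_MEMBERS,
    MoeResult,
    MoetResult,
    combine_moet,
    compute_moe,
    risk21_classify,
    ttc_screen,
)
from .sensitivity import contribution_to_variance

MOE_COLUMNS = [
    "analyte",
    "age_group",
    "scenario",
    "bound",
    "percentile",
    "pod_mg_kg_day",
    "moe",
    "target_moe",
    "verdict",
]


class DietaryRiskModel:
    """Cumulative dietary risk model for packaging-derived photoinitiators.

    Parameters
    ----------
    occurrence
        Concentration records (or anything accepted by
        :func:`bprisk.occurrence.group_records`).
    population
        Age groups with body-weight and intake-rate distributions.
    registry
        Hazard registry; the packaged registry is loaded when omitted.
    af
        Absorption fraction applied to every analyte (conservatively 1.0).
    sampling
        Scenario-2 concentration sampling: resample the bounded values
        empirically (default; together with common random numbers across
        bounds this preserves the LB <= UB ordering of every exposure
        statistic) or draw from the KS-selected fitted family (``"fitted"``).
    """

    def __init__(
        self,
        occurrence: Sequence[OccurrenceRecord],
        population: Sequence[PopulationGroup],
        registry: HazardRegistry | None = None,
        af: float = 1.0,
        sampling: Literal["fitted", "empirical"] = "empirical",
        generator_config: GeneratorConfig | None = None,
    ):
        self.occurrence = group_records(occurrence)
        self.population = list(population)
        self.registry = registry if registry is not None else load_registry()
        self.af = af
        self.sampling = sampling
        self.generator_config = generator_config
        if not self.population:
            raise ValueError("at least one population group is required")

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_synthetic(
        cls, config: GeneratorConfig | None = None, seed: int = 0, **kwargs
    ) -> "DietaryRiskModel":
        """Build the model on a freshly generated synthetic survey."""
        from .synthetic import generate_occurrence, generate_population

        if config is None:
            config = default_generator_config(seed=seed)
        records = generate_occurrence(config)
        groups = generate_population(config)
        return cls(records, groups, generator_config=config, **kwargs)

    @classmethod
    def from_csv(
        cls, occurrence_path, population_path, registry_path=None, **kwargs
    ) -> "DietaryRiskModel":
        from .synthetic import read_population_csv

        records = read_occurrence_csv(occurrence_path)
        groups = read_population_csv(population_path)
        registry = load_registry(registry_path) if registry_path else None
        return cls(records, groups, registry=registry, **kwargs)

    # -- helpers ------------------------------------------------------------

    def _analytes_for(self, scenario: int) -> list[str]:
        if scenario == 1:
            present = set(SML_MG_KG)
        else:
            present = {analyte for (_, analyte) in self.occurrence}
        return [a for a in ANALYTES if a in present]

    def _fully_detected(self, analyte: str) -> bool:
        found = False
        for (cat, a), recs in self.occurrence.items():
            if a != analyte:
                continue
            found = True
            if any(r.status != "detected" for r in recs):
                return False
        return found

    def _bounds_for(self, analyte: str, scenario: int) -> list[str]:
        if scenario == 1:
            # concentrations are fixed at the SML; censoring plays no role
            return ["not_applicable"]
        if self._fully_detected(analyte):
            # 100% detection: LB and UB coincide, a single run suffices
            return ["not_applicable"]
        return ["LB", "UB"]

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        scenario: int = 2,
        n_iterations: int = 10_000,
        seed: int = 0,
        age_groups: Sequence[str] | None = None,
        ttc_bw: float | None = None,
        compute_sensitivity: bool = True,
    ) -> "RiskAssessmentResults":
        """Run the Monte Carlo assessment for one exposure scenario."""
        if scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        groups = self.population
        if age_groups is not None:
            wanted = set(age_groups)
            groups = [g for g in groups if g.age_group in wanted]
            if not groups:
                raise ValueError("no matching age groups")

        analytes = self._analytes_for(scenario)
        add_results: list[AddDistribution] = []
        sens_rows: list[dict] = []
        for analyte in analytes:
            for bound in self._bounds_for(analyte, scenario):
                if scenario == 1:
                    spec = ScenarioSpec.scenario1(af=self.af)
                else:
                    spec = ScenarioSpec.scenario2(bound=bound, af=self.af, sampling=self.sampling)
                # sensitivity is reported at the conservative bound only
                want_sens = compute_sensitivity and bound != "LB"
                for grp in groups:
                    dist = simulate_add(
                        spec,
                        grp,
                        analyte,
                        occurrence=self.occurrence if scenario == 2 else None,
                        n_iter=n_iterations,
                        seed=seed,
                        keep_input_draws=want_sens,
                    )
                    if want_sens and np.ptp(dist.samples) > 0:
                        sens = contribution_to_variance(
                            dist.input_draws, dist.samples, analyte=analyte, age_group=grp.age_group
                        )
                        for name, pct in sens.ranked():
                            sens_rows.append(
                                {
                                    "analyte": analyte,
                                    "age_group": grp.age_group,
                                    "input": name,
                                    "contribution_pct": pct,
                                    "rank_correlation": sens.rank_correlations[name],
                                }
                            )
                    dist.input_draws = {}
                    add_results.append(dist)

        exposure = assemble_exposure_table(add_results)
        moe_df = self._moe_table(add_results)
        moet_df = self._moet_table(add_results, scenario)
        ttc_df = self._ttc_table(add_results, scenario, ttc_bw)
        risk21_df = self._risk21_table(add_results)
        sensitivity = pd.DataFrame(
            sens_rows,
            columns=["analyte", "age_group", "input", "contribution_pct", "rank_correlation"],
        )
        metadata = {
            "package": "bprisk",
            "version": _version,
            "scenario": scenario,
            "n_iterations": n_iterations,
            "seed": seed,
            "absorption_fraction": self.af,
            "sampling": self.sampling,
            "age_groups": [g.age_group for g in groups],
            "analytes": analytes,
            "config_sha256": self._config_hash(),
        }
        return RiskAssessmentResults(
            model=self,
            add_distributions=add_results,
            exposure=exposure,
            moe=moe_df,
            moet=moet_df,
            ttc=ttc_df,
            risk21=risk21_df,
            sensitivity=sensitivity,
            metadata=metadata,
        )

    def _config_hash(self) -> str | None:
        if self.generator_config is None:
            return None
        blob = json.dumps(self.generator_config.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()

    # -- table builders -----------------------------------------------------

    def _moe_table(self, add_results: list[AddDistribution]) -> pd.DataFrame:
        rows = []
        for dist in add_results:
            entry = self.registry.get(dist.analyte)
            if entry is None or not entry.profiles:
                continue
            for percentile, add in (("P50", dist.p50), ("P97.5", dist.p97_5)):
                for profile in entry.profiles:
                    moe = compute_moe(profile.pod_value, add)
                    res = MoeResult(
                        analyte=dist.analyte,
                        age_group=dist.age_group,
                        scenario=dist.scenario,
                        bound=dist.bound,
                        percentile=percentile,
                        moe=moe,
                        target_moe=profile.target_moe,
                        pod_value=profile.pod_value,
                        pod_type=profile.pod_type,
                        endpoint_class=profile.endpoint_class,
                        infinite=not np.isfinite(moe),
                    )
                    rows.append(
                        {
                            "analyte": res.analyte,
                            "age_group": res.age_group,
                            "scenario": res.scenario,
                            "bound": res.bound,
                            "percentile": res.percentile,
                            "pod_mg_kg_day": res.pod_value,
                            "pod_type": res.pod_type,
                            "endpoint_class": res.endpoint_class,
                            "primary": profile.primary,
                            "moe": res.moe,
                            "target_moe": res.target_moe,
                            "verdict": res.verdict,
                        }
                    )
        return pd.DataFrame(rows, columns=MOE_COLUMNS[:6] + ["pod_type", "endpoint_class", "primary", "moe", "target_moe", "verdict"])

    def _moet_table(self, add_results: list[AddDistribution], scenario: int) -> pd.DataFrame:
        # index primary-MOE inputs: (analyte, group, bound) -> (p50, p97.5)
        by_key = {(d.analyte, d.age_group, d.bound): d for d in add_results}
        groups = sorted({d.age_group for d in add_results})
        bounds = sorted({d.bound for d in add_results if d.analyte in MOET_MEMBERS})
        rows = []
        for grp in groups:
            for bound in bounds:
                for percentile in ("P50", "P97.5"):
                    moes: dict[str, float] = {}
                    for member in MOET_MEMBERS:
                        entry = self.registry.get(member)
                        if entry is None or entry.primary is None:
                            continue
                        dist = by_key.get((member, grp, bound)) or by_key.get(
                            (member, grp, "not_applicable")
                        )
                        if dist is None:
                            continue
                        add = dist.p50 if percentile == "P50" else dist.p97_5
                        moes[member] = compute_moe(entry.primary.pod_value, add)
                    if not moes:
                        continue
                    target = max(
                        self.registry[m].primary.target_moe for m in moes
                    )
                    res = MoetResult(
                        age_group=grp,
                        scenario=scenario,
                        bound=bound,
                        percentile=percentile,
                        members=tuple(moes),
                        moet=combine_moet(moes),
                        target=target,
                    )
                    rows.append(
                        {
                            "age_group": res.age_group,
                            "scenario": res.scenario,
                            "bound": res.bound,
                            "percentile": res.percentile,
                            "members": "+".join(res.members),
                            "moet": res.moet,
                            "target_moet": res.target,
                            "verdict": res.verdict,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["age_group", "scenario", "bound", "percentile", "members", "moet", "target_moet", "verdict"],
        )

    def _ttc_table(
        self, add_results: list[AddDistribution], scenario: int, ttc_bw: float | None
    ) -> pd.DataFrame:
        rows = []
        for dist in add_results:
            entry = self.registry.get(dist.analyte)
            if entry is None or not entry.ttc_only:
                continue
            if dist.bound == "LB":
                continue  # screening uses the conservative bound
            rule = self.registry.ttc_rule(entry.cramer_class, default_bw=ttc_bw)
            _, threshold_mg = ttc_threshold_per_bw(rule)
            verdict = ttc_screen(dist.analyte, dist.age_group, dist.p97_5, threshold_mg)
            rows.append(
                {
                    "analyte": dist.analyte,
                    "age_group": dist.age_group,
                    "scenario": scenario,
                    "bound": dist.bound,
                    "percentile": "P97.5",
                    "cramer_class": entry.cramer_class,
                    "exposure_mg_kg_day": verdict.exposure,
                    "threshold_mg_kg_day": verdict.threshold,
                    "verdict": verdict.verdict,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "analyte",
                "age_group",
                "scenario",
                "bound",
                "percentile",
                "cramer_class",
                "exposure_mg_kg_day",
                "threshold_mg_kg_day",
                "verdict",
            ],
        )

    def _risk21_table(self, add_results: list[AddDistribution]) -> pd.DataFrame:
        rows = []
        for dist in add_results:
            entry = self.registry.get(dist.analyte)
            if entry is None or not entry.profiles:
                continue
            if dist.bound == "LB":
                continue
            # the toxicity band spans points of departure; a TDI is already
            # divided by uncertainty factors and would misplace the band
            pods = [p.pod_value for p in entry.profiles if p.pod_type != "TDI"]
            if not pods:
                pods = [p.pod_value for p in entry.profiles]
            cell = risk21_classify(
                dist.analyte,
                dist.age_group,
                exposure_low=dist.p50,
                exposure_high=dist.p97_5,
                tox_low=min(pods),
                tox_high=max(pods),
                target_moe=entry.primary.target_moe if entry.primary else 100.0,
            )
            rows.append(
                {
                    "analyte": cell.analyte,
                    "age_group": cell.age_group,
                    "scenario": dist.scenario,
                    "bound": dist.bound,
                    "exposure_low_mg_kg_day": cell.exposure_low,
                    "exposure_high_mg_kg_day": cell.exposure_high,
                    "tox_low_mg_kg_day": cell.tox_low,
                    "tox_high_mg_kg_day": cell.tox_high,
                    "classification": cell.classification,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "analyte",
                "age_group",
                "scenario",
                "bound",
                "exposure_low_mg_kg_day",
                "exposure_high_mg_kg_day",
                "tox_low_mg_kg_day",
                "tox_high_mg_kg_day",
                "classification",
            ],
        )


@dataclass
class RiskAssessmentResults:
    """Fitted assessment: exposure, risk and sensitivity tables.

    Attributes
    ----------
    exposure : DataFrame
        P50/P97.5 ADD (mg/kg bw/day) per analyte x age group x bound.
    moe : DataFrame
        Margin of exposure per hazard profile and percentile, with verdicts.
    moet : DataFrame
        Cumulative MOE_T for the shared-endpoint members.
    ttc : DataFrame
        TTC screening verdicts for data-poor analytes.
    risk21 : DataFrame
        Exposure-vs-toxicity band classification per analyte x age group.
    sensitivity : DataFrame
        Contribution-to-variance of each stochastic input.
    """

    model: DietaryRiskModel
    add_distributions: list[AddDistribution]
    exposure: pd.DataFrame
    moe: pd.DataFrame
    moet: pd.DataFrame
    ttc: pd.DataFrame
    risk21: pd.DataFrame
    sensitivity: pd.DataFrame
    metadata: dict

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        md = self.metadata
        lines = [
            "Cumulative dietary risk assessment (benzophenone-type photoinitiators)",
            "=" * 72,
            f"scenario: {md['scenario']}    iterations: {md['n_iterations']:,}    seed: {md['seed']}",
            f"absorption fraction: {md['absorption_fraction']}    sampling: {md['sampling']}",
            f"analytes: {', '.join(md['analytes'])}",
            f"age groups: {', '.join(md['age_groups'])}",
            "",
            "Exposure (P97.5 ADD, mg/kg bw/day), maximum over age groups:",
        ]
        worst = self.exposure.groupby(["analyte", "bound"])["p97_5_mg_kg_day"].max()
        for (analyte, bound), value in worst.items():
            lines.append(f"  {analyte:7s} [{bound:>14s}]  {value:10.4g}")
        primary = self.moe[self.moe["primary"]] if "primary" in self.moe else self.moe
        if len(primary):
            lines += ["", "Margin of exposure (primary POD, P97.5), minimum over age groups:"]
            worst_moe = primary[primary["percentile"] == "P97.5"].groupby(["analyte", "bound"])["moe"].min()
            for (analyte, bound), value in worst_moe.items():
                target = float(
                    primary[primary["analyte"] == analyte]["target_moe"].iloc[0]
                )
                flag = "acceptable" if value >= target else "CONCERN"
                lines.append(f"  {analyte:7s} [{bound:>14s}]  MOE {value:12.4g}  target {target:g}  {flag}")
        if len(self.moet):
            lines += ["", "Cumulative MOE_T (members: " + self.moet['members'].iloc[0] + "):"]
            worst_moet = self.moet[self.moet["percentile"] == "P97.5"]
            row = worst_moet.loc[worst_moet["moet"].idxmin()]
            lines.append(
                f"  minimum MOE_T {row['moet']:.4g} (age {row['age_group']}, bound {row['bound']})"
                f"  target {row['target_moet']:g}  -> {row['verdict']}"
            )
        if len(self.ttc):
            n_below = int((self.ttc["verdict"] == "below_threshold").sum())
            lines += [
                "",
                f"TTC screening: {n_below}/{len(self.ttc)} age-group exposures below "
                f"{self.ttc['threshold_mg_kg_day'].iloc[0]:g} mg/kg bw/day",
            ]
        if len(self.risk21):
            counts = self.risk21["classification"].value_counts().to_dict()
            lines += ["", f"RISK21 classifications: {counts}"]
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, outdir, float_format: str = "%.4g") -> dict[str, Path]:
        """Write all result tables and run metadata to ``outdir``.

        Output is deterministic for a fixed model configuration and seed
        (no timestamps), so identical runs produce byte-identical files.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        tables = {
            "exposure": self.exposure,
            "moe": self.moe,
            "moet": self.moet,
            "ttc": self.ttc,
            "risk21": self.risk21,
            "sensitivity": self.sensitivity,
        }
        for name, df in tables.items():
            path = outdir / f"{name}.csv"
            df.to_csv(path, index=False, float_format=float_format, lineterminator="\r\n")
            paths[name] = path
        meta_path = outdir / "run_metadata.json"
        with open(meta_path, "w") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths["metadata"] = meta_path
        return paths

    # -- plotting -----------------------------------------------------------

    def plot_risk21(self, ax=None):
        """Exposure band vs toxicity band per analyte (log-log RISK21 view)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        data = self.risk21
        colors = {"low": "tab:green", "moderate": "tab:orange", "high": "tab:red"}
        for analyte, sub in data.groupby("analyte"):
            ax.scatter(
                sub["exposure_high_mg_kg_day"],
                sub["tox_low_mg_kg_day"],
                label=analyte,
                c=[colors[c] for c in sub["classification"]],
                edgecolors="k",
                s=40,
            )
        lims = np.array([1e-8, 1e3])
        ax.plot(lims, lims, "k--", lw=1, label="exposure = toxicity")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("P97.5 ADD (mg/kg bw/day)")
        ax.set_ylabel("POD (mg/kg bw/day)")
        ax.set_title("RISK21 exposure vs toxicity")
        ax.legend(fontsize=8)
        return ax

    def plot_ttc(self, ax=None):
        """Per-age-group exposure of TTC-screened analytes vs the threshold."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        data = self.ttc
        if not len(data):
            raise ValueError("no TTC screening rows in these results")
        for analyte, sub in data.groupby("analyte"):
            ax.bar(sub["age_group"], sub["exposure_mg_kg_day"], label=analyte, alpha=0.8)
        ax.axhline(
            float(data["threshold_mg_kg_day"].iloc[0]),
            color="r",
            ls="--",
            label="TTC threshold",
        )
        ax.set_yscale("log")
        ax.set_ylabel("P97.5 UB ADD (mg/kg bw/day)")
        ax.set_xlabel("age group")
        ax.legend(fontsize=8)
        return ax
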