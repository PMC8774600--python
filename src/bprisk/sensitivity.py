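"""Contribution-to-variance sensitivity analysis.

Each stochastic input's influence on the simulated ADD is summarized by its
Spearman rank correlation with the output; the contribution of input *i* is
the normalized squared rank correlation

    contribution_i = 100 * r_i^2 / sum_j r_j^2   [percent],

the convention used by spreadsheet Monte Carlo tools for "contribution to
variance" tornado charts.  The sign of r is kept as metadata (body weight,
which divides the dose, is expected negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

#: rank correlations below this magnitude are reported as exactly 0%
NOISE_FLOOR = 0.01

METHOD = "normalized squared Spearman rank correlation"


@dataclass
class SensitivityResult:
    analyte: str
    age_group: str
    contributions: dict[str, float]  # percent, summing to 100 over nonzero inputs
    rank_correlations: dict[str, float] = field(default_factory=dict)
    method: str = METHOD

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.contributions.items(), key=lambda kv: kv[1], reverse=True)


def contribution_to_variance(
    input_draws: Mapping[str, Sequence[float]],
    output_draws: Sequence[float],
    analyte: str = "",
    age_group: str = "",
) -> SensitivityResult:
    """Apportion output variance across stochastic inputs by rank correlation."""
    output = np.asarray(output_draws, dtype=float)
    if output.size < 100:
        raise ValueError("need at least 100 draws")
    if np.ptp(output) == 0:
        raise ValueError("output draws are constant; no variance to apportion")

    correlations: dict[str, float] = {}
    for name, draws in input_draws.items():
        arr = np.asarray(draws, dtype=float)
        if arr.size != output.size:
            raise ValueError(f"input {name!r} length {arr.size} != output length {output.size}")
        if np.ptp(arr) == 0:
            warnings.warn(f"input {name!r} is constant; contribution set to 0", stacklevel=2)
            correlations[name] = 0.0
            continue
        r = stats.spearmanr(arr, output).statistic
        correlations[name] = float(r)

    squared = {
        name: (r * r if abs(r) >= NOISE_FLOOR else 0.0) for name, r in correlations.items()
    }
    total = sum(squared.values())
    if total == 0:
        contributions = {name: 0.0 for name in squared}
    else:
        contributions = {name: 100.0 * s / total for name, s in squared.items()}
    return SensitivityResult(
        analyte=analyte,
        age_group=age_group,
        contributions=contributions,
        rank_correlations=correlations,
    )
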