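"""Relative qRT-PCR quantification: standard-curve efficiencies and
efficiency-corrected expression ratios.

A gene's amplification efficiency E is fitted from a serial-dilution
standard curve (mean Cq against log10 relative input; E = 10^(-1/slope), so
the ideal doubling reaction has slope -3.3219 and E = 2).  Relative
expression is the efficiency-corrected ratio

    ratio = E_target^dCq_target / E_reference^dCq_reference

with dCq = Cq(control) - Cq(treated), so over-expression in disease yields
ratios above 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

#: efficiencies outside this band are fitted but flagged implausible
PLAUSIBLE_E = (1.6, 2.2)
#: replicates further than this many cycles from the triplicate median are
#: discarded before averaging
REPLICATE_OUTLIER_CYCLES = 0.5


@dataclass
class DilutionSeries:
    """Cq values for one gene over a serial dilution, replicates x levels.

    ``cq`` has one row per dilution level (level 0 = undiluted input,
    level i = input / dilution_step**i), columns are replicates.
    """

    gene_id: str
    dilution_step: float
    cq: np.ndarray

    def __post_init__(self) -> None:
        self.cq = np.asarray(self.cq, dtype=float)
        if self.cq.ndim != 2:
            raise ValueError("cq must be a 2-D array: levels x replicates")
        if self.cq.shape[0] < 3:
            raise ValueError("need >= 3 dilution levels")
        if (self.cq <= 0).any():
            raise ValueError("Cq values must be positive")
        if self.dilution_step <= 1:
            raise ValueError("dilution_step must exceed 1")


@dataclass(frozen=True)
class PfafflInput:
    e_target: float
    e_reference: float
    dct_target: float  # Cq(control) - Cq(treated), cycles
    dct_reference: float

    def __post_init__(self) -> None:
        if self.e_target <= 1 or self.e_reference <= 1:
            raise ValueError("amplification efficiencies must exceed 1")


@dataclass
class EfficiencyFit:
    gene_id: str
    efficiency: float
    slope: float
    intercept: float
    r_squared: float
    plausible: bool
    level_means: np.ndarray


def _summarize_replicates(row: np.ndarray) -> float:
    """Mean Cq after discarding replicates far from the replicate median."""
    med = float(np.median(row))
    kept = row[np.abs(row - med) <= REPLICATE_OUTLIER_CYCLES]
    if kept.size == 0:
        kept = row
    return float(np.mean(kept))


def amplification_efficiency(series: DilutionSeries) -> EfficiencyFit:
    """Least-squares standard-curve fit of mean Cq vs log10 relative input.

    Mean Cq must increase strictly with dilution (less input, later
    quantification cycle); a non-monotone series is rejected naming the
    offending level.  E = 10^(-1/slope).
    """
    means = np.array([_summarize_replicates(row) for row in series.cq])
    for lvl in range(1, means.size):
        if means[lvl] <= means[lvl - 1]:
            raise ValueError(
                f"{series.gene_id}: mean Cq not strictly increasing at "
                f"dilution level {lvl} ({means[lvl - 1]:.3f} -> {means[lvl]:.3f})"
            )
    # relative input of level i is step**-i
    x = -np.arange(means.size) * math.log10(series.dilution_step)
    fit = stats.linregress(x, means)
    e = 10.0 ** (-1.0 / fit.slope)
    return EfficiencyFit(
        gene_id=series.gene_id,
        efficiency=float(e),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        plausible=PLAUSIBLE_E[0] <= e <= PLAUSIBLE_E[1],
        level_means=means,
    )


def pfaffl_ratio(inp: PfafflInput) -> float:
    """Efficiency-corrected relative expression ratio.

    With equal efficiencies E this reduces to the ddCq identity
    E^(dct_target - dct_reference).
    """
    return (inp.e_target**inp.dct_target) / (inp.e_reference**inp.dct_reference)
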