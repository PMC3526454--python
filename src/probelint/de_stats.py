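"""Nonparametric differential expression and cross-study baseline checks.

Array intensities are non-normal with unequal class variances, so location
differences are tested with the Wilcoxon two-sample rank-sum test: exact
two-sided p-values by enumeration of the null rank-sum distribution for
small tie-free samples, a tie-corrected normal approximation with
continuity correction otherwise.  Multiplicity is handled by
Benjamini-Hochberg FDR (default) or Bonferroni.  DE lists from different
pipelines are reconciled against the probe verdict ledger, and control
baselines from two studies are compared by per-gene correlation with a
Lowess trend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess
from statsmodels.stats.multitest import multipletests

from .measurement_qc import IntensityMatrix
from .probe_filters import FilterVerdict

logger = logging.getLogger(__name__)

EXACT_MAX_N = 25


@dataclass(frozen=True)
class DEResult:
    gene_id: str
    probe_id: str
    statistic: float  # rank sum of the disease group
    p_raw: float
    p_adj: float
    direction: str  # up/down in disease vs control, from medians
    n_control: int
    n_disease: int
    significant: bool

    def __post_init__(self) -> None:
        if not (0 <= self.p_raw <= 1 and 0 <= self.p_adj <= 1):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adj < self.p_raw - 1e-12:
            raise ValueError("adjusted p cannot be below raw p")


@dataclass
class CorrelationReport:
    shared_gene_ids: list[str]
    r_squared: float
    lowess_curve: np.ndarray  # (m, 2) ordered (x, smoothed y)

    def __post_init__(self) -> None:
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _ranksum_counts(n_a: int, n: int) -> np.ndarray:
    """counts[w] = number of size-n_a subsets of ranks {1..n} with sum w.

    Classic subset-sum dynamic program; the total is C(n, n_a), well within
    int64 for n <= 25.
    """
    max_w = n * (n + 1) // 2
    dp = np.zeros((n_a + 1, max_w + 1), dtype=np.int64)
    dp[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n_a), 0, -1):
            dp[k, r:] += dp[k - 1, : max_w + 1 - r]
    return dp[n_a]


def exact_ranksum_pvalue(w_obs: float, n_a: int, n: int) -> float:
    """Two-sided exact p for a tie-free rank sum: total probability of rank
    sums at least as far from the null mean n_a(n+1)/2 as observed."""
    counts = _ranksum_counts(n_a, n)
    two_mu = n_a * (n + 1)
    dev = abs(2 * int(round(w_obs)) - two_mu)
    w = np.arange(counts.size)
    mask = np.abs(2 * w - two_mu) >= dev
    return float(counts[mask].sum() / counts.sum())


def wilcoxon_unpaired(
    group_a: Sequence[float],
    group_b: Sequence[float],
    continuity: bool = True,
    exact: bool | None = None,
) -> tuple[float, float]:
    """Rank-sum statistic of group A and its two-sided p-value.

    Exact enumeration is used when n_a + n_b <= 25 and there are no ties
    (and not explicitly disabled); otherwise the normal approximation with
    midranks, tie-corrected variance and optional continuity correction.
    Deterministic and symmetric under label swap.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    combined = np.concatenate([a, b])
    ranks = stats.rankdata(combined)
    w = float(ranks[:n_a].sum())
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    use_exact = (n <= EXACT_MAX_N and not has_ties) if exact is None else exact
    if use_exact and has_ties:
        use_exact = False  # exact enumeration is defined for distinct ranks
    if use_exact:
        return w, exact_ranksum_pvalue(w, n_a, n)
    mu = n_a * (n + 1) / 2.0
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return w, 1.0
    dev = abs(w - mu)
    if continuity:
        dev = max(0.0, dev - 0.5)
    z = dev / np.sqrt(var)
    return w, float(min(1.0, 2 * stats.norm.sf(z)))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

_METHOD_MAP = {"bh_fdr": "fdr_bh", "bonferroni": "bonferroni"}


def adjust_pvalues(pvalues: Sequence[float], method: str = "bh_fdr") -> np.ndarray:
    """BH step-up or Bonferroni adjusted p-values, input order preserved."""
    if method not in _METHOD_MAP:
        raise ValueError(f"unknown correction method {method!r}")
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method=_METHOD_MAP[method])
    return adjusted


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def run_de(
    matrix: IntensityMatrix,
    alpha: float = 0.05,
    correction: str = "bh_fdr",
    gene_of: Mapping[str, str] | None = None,
    continuity: bool = True,
) -> list[DEResult]:
    """Per-probe Wilcoxon rank-sum across classes with multiplicity control.

    Probes with one or two array probes per gene are tested separately and
    reported with their gene annotation (no probe-to-gene summarization).
    Probes with missing values in either class are excluded with a log
    entry, mirroring the valid-in-every-array prerequisite.  Direction is
    the sign of the disease-minus-control median difference.  Results are
    sorted by raw p-value with stable tie order by gene id.
    """
    gene_of = gene_of or {}
    ctrl = matrix.samples_in("control")
    dis = matrix.samples_in("disease")
    if not ctrl or not dis:
        raise ValueError("both classes must be represented")
    tested: list[tuple[str, str, float, float, str]] = []
    for probe in matrix.values.index:
        a = matrix.values.loc[probe, dis].to_numpy(float)  # disease
        b = matrix.values.loc[probe, ctrl].to_numpy(float)  # control
        if np.isnan(a).any() or np.isnan(b).any():
            logger.info("probe %s excluded from DE: missing values", probe)
            continue
        w, p = wilcoxon_unpaired(a, b, continuity=continuity)
        diff = float(np.median(a) - np.median(b))
        direction = "down" if diff < 0 else "up"
        tested.append((probe, gene_of.get(probe, probe), w, p, direction))
    if not tested:
        return []
    adjusted = adjust_pvalues([t[3] for t in tested], method=correction)
    results = [
        DEResult(
            gene_id=gene,
            probe_id=probe,
            statistic=w,
            p_raw=p,
            p_adj=float(p_adj),
            direction=direction,
            n_control=len(ctrl),
            n_disease=len(dis),
            significant=bool(p_adj < alpha),
        )
        for (probe, gene, w, p, direction), p_adj in zip(tested, adjusted)
    ]
    results.sort(key=lambda r: (r.p_raw, r.gene_id, r.probe_id))
    return results


@dataclass
class OverlapReport:
    shared: list[str]
    a_only: list[str]
    b_only: list[str]
    exclusion_reasons: dict[str, str]  # discordant id -> ledger flag summary


def compare_de_lists(
    list_a: Iterable[str],
    list_b: Iterable[str],
    ledger_a: Mapping[str, FilterVerdict] | None = None,
    ledger_b: Mapping[str, FilterVerdict] | None = None,
) -> OverlapReport:
    """Set decomposition of two DE lists with ledger-joined reasons.

    For an id found only in one list, the other pipeline's verdict ledger is
    consulted: if that pipeline flagged the probe, the flag explains the
    discordance (e.g. "excluded by cross_hyb").
    """
    sa, sb = set(list_a), set(list_b)
    reasons: dict[str, str] = {}
    for gid in sorted(sb - sa):
        v = (ledger_a or {}).get(gid)
        if v is not None and v.effective_flags:
            reasons[gid] = "excluded by " + ",".join(sorted(v.effective_flags))
    for gid in sorted(sa - sb):
        v = (ledger_b or {}).get(gid)
        if v is not None and v.effective_flags:
            reasons[gid] = "excluded by " + ",".join(sorted(v.effective_flags))
    return OverlapReport(
        shared=sorted(sa & sb),
        a_only=sorted(sa - sb),
        b_only=sorted(sb - sa),
        exclusion_reasons=reasons,
    )


# ---------------------------------------------------------------------------
# cross-study baseline correlation
# ---------------------------------------------------------------------------


def control_correlation(
    matrix_a: IntensityMatrix,
    matrix_b: IntensityMatrix,
    gene_of_a: Mapping[str, str] | None = None,
    gene_of_b: Mapping[str, str] | None = None,
    lowess_frac: float = 0.3,
) -> CorrelationReport:
    """Per-gene control-sample means compared across two studies.

    Shared genes are matched via the probe-to-gene mappings (identity by
    default); each gene's value is the mean over control arrays (and over
    multiple probes where present).  Reports the squared Pearson correlation
    and a Lowess trend (tricube local linear, 3 robustness iterations).
    Symmetric in its arguments up to axis exchange.
    """

    def per_gene_means(m: IntensityMatrix, gene_of: Mapping[str, str] | None):
        cols = m.samples_in("control")
        if not cols:
            raise ValueError("matrix has no control samples")
        probe_means = m.values[cols].mean(axis=1, skipna=True)
        genes: dict[str, list[float]] = {}
        for probe, val in probe_means.items():
            if np.isnan(val):
                continue
            gene = (gene_of or {}).get(probe, probe)
            genes.setdefault(gene, []).append(float(val))
        return {g: float(np.mean(v)) for g, v in genes.items()}

    ga = per_gene_means(matrix_a, gene_of_a)
    gb = per_gene_means(matrix_b, gene_of_b)
    shared = sorted(set(ga) & set(gb))
    if len(shared) < 2:
        raise ValueError(f"need >= 2 shared genes, found {len(shared)}")
    x = np.array([ga[g] for g in shared])
    y = np.array([gb[g] for g in shared])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        r2 = 1.0 if np.allclose(x - x.mean(), y - y.mean()) else 0.0
    else:
        r2 = float(stats.pearsonr(x, y)[0] ** 2)
    curve = _sm_lowess(y, x, frac=lowess_frac, it=3)
    return CorrelationReport(
        shared_gene_ids=shared, r_squared=min(1.0, r2), lowess_curve=curve
    )
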