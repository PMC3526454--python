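"""Background estimation, the valid-in-every-array measurement filter, and
sample outlier detection.

The scanner's noise floor is estimated from probes that (a) pass the
uniqueness filters, (b) fold into very stable monomer structures
(dG < -10 kcal/mol, hence barely responsive to target), and (c) map to genes
not expected to be expressed in the sampled tissue: their measurements are
pure background.  The per-class mean (or median, or a Lowess floor) of those
measurements becomes the class cutoff.  A probe is retained for testing only
when its measurement exceeds the cutoff in every array of the required
class grouping; samples whose per-probe mean signal or above-cutoff probe
count strays more than k standard deviations from their class are outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .probe_filters import FilterVerdict
from .thermo import BACKGROUND_DG_CUTOFF

logger = logging.getLogger(__name__)

CLASS_LABELS = ("control", "disease")
CHANNEL_LABELS = ("sample_channel", "pooled_reference")

#: flags whose presence disqualifies a probe from *background candidacy*
#: (sequence-uniqueness problems); delta_g and poly_g do not, since stable
#: folders are exactly what the background estimate is built from.
UNIQUENESS_FLAGS = frozenset({"cross_hyb", "loss_of_target", "snp", "repeat"})


@dataclass
class IntensityMatrix:
    """log10 intensities, probes x samples, with class and channel labels.

    ``values`` may contain NaN where a raw measurement was removed at parse
    time (negative or missing spot intensity); it never contains infinities
    or negative "intensities" on the log scale's raw side.
    """

    values: pd.DataFrame
    class_of: pd.Series
    channel_of: pd.Series | None = None

    def __post_init__(self) -> None:
        self.class_of = pd.Series(self.class_of)
        missing = [s for s in self.values.columns if s not in self.class_of.index]
        if missing:
            raise ValueError(f"samples without class labels: {missing}")
        bad = set(self.class_of.loc[list(self.values.columns)]) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if np.isinf(self.values.to_numpy()).any():
            raise ValueError("intensity matrix contains infinite values")
        if self.channel_of is None:
            self.channel_of = pd.Series(
                "sample_channel", index=list(self.values.columns)
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, cls: str) -> list[str]:
        return [s for s in self.values.columns if self.class_of[s] == cls]

    def classes(self) -> list[str]:
        return [c for c in CLASS_LABELS if self.samples_in(c)]


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata; RIN gating (> 5.0) is a selection predicate for
    downstream assays, not an intensity filter."""

    sample_id: str
    sample_class: str
    rin: float | None = None

    def __post_init__(self) -> None:
        if self.rin is not None and not (0 <= self.rin <= 10):
            raise ValueError("RIN must lie in [0, 10]")

    def passes_rin(self, minimum: float = 5.0) -> bool:
        return self.rin is not None and self.rin > minimum


@dataclass
class BackgroundEstimate:
    cutoffs: dict[str, float]  # per-class log10 cutoff
    method: str
    candidate_probe_ids: list[str]

    def __post_init__(self) -> None:
        if not self.candidate_probe_ids:
            raise ValueError("candidate probe set is empty")
        for cls, c in self.cutoffs.items():
            if not np.isfinite(c):
                raise ValueError(f"non-finite cutoff for class {cls!r}")


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


def select_background_candidates(
    verdicts: Iterable[FilterVerdict],
    monomer_dg: Mapping[str, float],
    probe_gene: Mapping[str, str],
    unexpressed_gene_ids: Iterable[str],
    dg_cutoff: float = BACKGROUND_DG_CUTOFF,
) -> list[str]:
    """Probes usable for background estimation.

    Uniqueness-allowed (no cross-hyb / loss-of-target / SNP / repeat flag
    outstanding), very stably folded (monomer dG strictly below dg_cutoff),
    and mapped to a gene in the unexpressed list.
    """
    unexpressed = set(unexpressed_gene_ids)
    out = []
    for v in verdicts:
        if v.effective_flags & UNIQUENESS_FLAGS:
            continue
        dg = monomer_dg.get(v.probe_id)
        if dg is None or dg >= dg_cutoff:
            continue
        if probe_gene.get(v.probe_id) not in unexpressed:
            continue
        out.append(v.probe_id)
    if not out:
        raise ValueError(
            "no background candidates: relax dg_cutoff (probes must fold "
            f"below {dg_cutoff} kcal/mol and map to unexpressed genes)"
        )
    return sorted(out)


def estimate_background(
    matrix: IntensityMatrix,
    candidates: Sequence[str],
    method: str = "stable_unexpressed_mean",
    monomer_dg: Mapping[str, float] | None = None,
    lowess_frac: float = 0.3,
) -> BackgroundEstimate:
    """Per-class background cutoff from candidate-probe measurements.

    mean/median methods pool candidate values across a class's arrays;
    ``lowess_floor`` smooths per-probe mean intensity against monomer dG and
    averages the fitted values over the candidate (very stable) probes,
    giving the intensity floor of the dG-vs-signal relation.
    """
    missing = [p for p in candidates if p not in matrix.values.index]
    if missing:
        raise ValueError(f"candidates absent from matrix: {missing[:5]}")
    cutoffs: dict[str, float] = {}
    for cls in CLASS_LABELS:
        cols = matrix.samples_in(cls)
        if not cols:
            raise ValueError(f"class {cls!r} has zero arrays")
        block = matrix.values.loc[list(candidates), cols].to_numpy(float)
        vals = block[np.isfinite(block)]
        if vals.size == 0:
            raise ValueError(f"class {cls!r} has no finite candidate values")
        if method == "stable_unexpressed_mean":
            cutoffs[cls] = float(np.mean(vals))
        elif method == "stable_unexpressed_median":
            cutoffs[cls] = float(np.median(vals))
        elif method == "lowess_floor":
            if monomer_dg is None:
                raise ValueError("lowess_floor requires monomer_dg values")
            from statsmodels.nonparametric.smoothers_lowess import lowess

            probes = [p for p in matrix.values.index if p in monomer_dg]
            x = np.array([monomer_dg[p] for p in probes])
            y = matrix.values.loc[probes, cols].mean(axis=1).to_numpy(float)
            keep = np.isfinite(x) & np.isfinite(y)
            fitted = lowess(y[keep], x[keep], frac=lowess_frac, it=3)
            cand = set(candidates)
            mask = np.array([p in cand for p in np.array(probes)[keep]])
            order = np.argsort(x[keep], kind="stable")
            fit_y = np.empty_like(fitted[:, 1])
            fit_y[order] = fitted[:, 1]
            cutoffs[cls] = float(np.mean(fit_y[mask]))
        else:
            raise ValueError(f"unknown background method {method!r}")
    return BackgroundEstimate(
        cutoffs=cutoffs, method=method, candidate_probe_ids=list(candidates)
    )


# ---------------------------------------------------------------------------
# measurement filter
# ---------------------------------------------------------------------------


def apply_measurement_filter(
    matrix: IntensityMatrix,
    bg: BackgroundEstimate,
    mode: str = "both",
) -> tuple[list[str], IntensityMatrix, pd.DataFrame]:
    """Keep probes with a valid measurement in every array of a class.

    A measurement is valid when it strictly exceeds the class cutoff (NaN is
    never valid).  ``mode='both'`` requires validity in every array of both
    classes (the default for probes entering differential testing);
    ``mode='either'`` accepts per-class validity in at least one class.
    Returns retained probe ids, the filtered matrix, and a table of removal
    reasons (probe, class, failing sample, value, cutoff).
    """
    if mode not in ("both", "either"):
        raise ValueError("mode must be 'both' or 'either'")
    classes = matrix.classes()
    per_class_ok: dict[str, pd.Series] = {}
    for cls in classes:
        cols = matrix.samples_in(cls)
        block = matrix.values[cols]
        per_class_ok[cls] = (block > bg.cutoffs[cls]).all(axis=1) & block.notna().all(
            axis=1
        )
    ok_frame = pd.DataFrame(per_class_ok)
    retained_mask = ok_frame.all(axis=1) if mode == "both" else ok_frame.any(axis=1)
    retained = [p for p in matrix.values.index if retained_mask[p]]
    failures = []
    for probe in matrix.values.index[~retained_mask]:
        for cls in classes:
            cutoff = bg.cutoffs[cls]
            for s in matrix.samples_in(cls):
                v = matrix.values.at[probe, s]
                if not (v > cutoff):
                    failures.append(
                        {
                            "probe_id": probe,
                            "class": cls,
                            "sample": s,
                            "value": v,
                            "cutoff": cutoff,
                        }
                    )
    filtered = IntensityMatrix(
        values=matrix.values.loc[retained].copy(),
        class_of=matrix.class_of.copy(),
        channel_of=None if matrix.channel_of is None else matrix.channel_of.copy(),
    )
    logger.info(
        "measurement filter: %d of %d probes retained",
        len(retained),
        matrix.values.shape[0],
    )
    return retained, filtered, pd.DataFrame(
        failures, columns=["probe_id", "class", "sample", "value", "cutoff"]
    )


# ---------------------------------------------------------------------------
# sample outliers
# ---------------------------------------------------------------------------


def detect_sample_outliers(
    matrix: IntensityMatrix,
    k: float = 2.0,
    bg: BackgroundEstimate | None = None,
    leave_one_out: bool = True,
) -> tuple[list[str], pd.DataFrame]:
    """Flag samples straying more than k SD from their class on either the
    mean signal per probe or the number of above-cutoff probes.

    Strict inequality: a sample sitting exactly at k SD is kept.  By default
    the class mean and SD exclude the candidate sample (leave-one-out), which
    keeps a gross outlier from masking itself by inflating the class SD;
    ``leave_one_out=False`` evaluates against statistics of the whole class.
    Population (ddof=0) standard deviations are used.  Requires >= 3 samples
    per class.  Invariant to sample order and to adding a constant.
    """
    rows = []
    outliers: list[str] = []
    for cls in matrix.classes():
        cols = matrix.samples_in(cls)
        if len(cols) < 3:
            raise ValueError(f"class {cls!r} needs >= 3 samples, has {len(cols)}")
        block = matrix.values[cols]
        mean_sig = block.mean(axis=0, skipna=True)
        if bg is not None:
            counts = (block > bg.cutoffs[cls]).sum(axis=0).astype(float)
        else:
            counts = block.notna().sum(axis=0).astype(float)
        flags: dict[str, tuple[float, float]] = {}
        for s in cols:
            zs = []
            for series in (mean_sig, counts):
                if leave_one_out:
                    others = series.drop(s).to_numpy(float)
                else:
                    others = series.to_numpy(float)
                m = float(np.mean(others))
                sd = float(np.std(others, ddof=0))
                dev = abs(float(series[s]) - m)
                if sd == 0.0:
                    z = 0.0 if dev == 0.0 else np.inf
                else:
                    z = dev / sd
                zs.append(z)
            flags[s] = (zs[0], zs[1])
        for s in cols:
            z_mean, z_count = flags[s]
            flagged = (z_mean > k) or (z_count > k)
            if flagged:
                outliers.append(s)
            rows.append(
                {
                    "sample": s,
                    "class": cls,
                    "mean_signal": float(mean_sig[s]),
                    "n_valid": float(counts[s]),
                    "z_mean_signal": z_mean,
                    "z_probe_count": z_count,
                    "outlier": flagged,
                }
            )
    return sorted(outliers), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# distribution diagnostics
# ---------------------------------------------------------------------------


@dataclass
class DistributionReport:
    f_statistic: float
    f_pvalue: float
    shapiro: dict[str, tuple[float, float] | None]
    qq: dict[str, tuple[np.ndarray, np.ndarray]]


def distribution_checks(
    group_a: Sequence[float], group_b: Sequence[float]
) -> DistributionReport:
    """Variance-equality F test, Shapiro-Wilk normality per group, QQ pairs.

    The F statistic is var(A)/var(B) with sample variances (ddof=1) and a
    two-sided p-value; a constant group's normality test is undefined and
    reported as None.  QQ output pairs theoretical normal quantiles with the
    ordered sample, ready for plotting.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if vb == 0 and va == 0:
        f_stat, f_p = 1.0, 1.0
    elif vb == 0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = float(va / vb)
        cdf = stats.f.cdf(f_stat, len(a) - 1, len(b) - 1)
        f_p = float(min(1.0, 2 * min(cdf, 1 - cdf)))
    shapiro: dict[str, tuple[float, float] | None] = {}
    qq: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for name, vals in (("A", a), ("B", b)):
        if np.ptp(vals) == 0:
            shapiro[name] = None  # constant sample: test undefined
        else:
            w, p = stats.shapiro(vals)
            shapiro[name] = (float(w), float(p))
        (osm, osr), _ = stats.probplot(vals, dist="norm")
        qq[name] = (osm, osr)
    return DistributionReport(f_statistic=f_stat, f_pvalue=f_p, shapiro=shapiro, qq=qq)
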