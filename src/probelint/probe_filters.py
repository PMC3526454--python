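"""Sequence-property probe filters and the per-probe verdict ledger.

Each filter answers one question about a probe's physical or biological
fitness as an expression sensor:

* cross-hybridization -- does a near-identical secondary genomic locus
  (Kane criteria) inside an *expressed* region form a stable enough
  heteroduplex to contribute signal?
* loss of target -- does the probe still anchor to the reference inside a
  single exon, as designed?
* SNP load -- do four or more known variant sites fall under the probe's
  binding footprint?
* poly-G -- does the probe contain a run of four or more guanines
  (associated with anomalous signal at both intensity extremes)?
* repeat -- does the probe share a long exact substring with a repeat
  element (LINE/SINE/Alu) library entry?

The filters are order-independent: each contributes a flag to a per-probe
:class:`FilterVerdict`, and a probe is allowed iff no flag remains after any
explicit add-backs (e.g. SNP-flagged probes restored for genotyped samples).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome_map import AnnotationSet, GenomeHit, ProbeRecord, SnpRecord, revcomp

FLAG_NAMES = ("cross_hyb", "loss_of_target", "snp", "delta_g", "poly_g", "repeat")

DEFAULT_MAX_SNPS = 4
DEFAULT_POLYG_MIN_RUN = 4
DEFAULT_REPEAT_MIN_MATCH = 15


@dataclass(frozen=True)
class KaneThresholds:
    """Empirical specificity thresholds for long-oligo cross-hybridization.

    A secondary locus can contribute detectable signal when overall identity
    is high (the count arm: >= min_matches identical bases AND identity
    fraction >= min_identity_fraction) or when it shares a long perfect
    stretch (the run arm: >= min_contiguous_run consecutive matches).  The
    two count-based criteria are deliberately one conjunctive arm; the run
    criterion is an independent mechanism, hence the disjunction.
    """

    min_matches: int = 50
    min_identity_fraction: float = 0.85
    min_contiguous_run: int = 15

    def __post_init__(self) -> None:
        if not (0 < self.min_identity_fraction <= 1):
            raise ValueError("min_identity_fraction must be in (0, 1]")
        if self.min_contiguous_run < 1:
            raise ValueError("min_contiguous_run must be >= 1")


def kane_flag(hit: GenomeHit, th: KaneThresholds | None = None) -> bool:
    """True if the hit is similar enough to cross-hybridize."""
    th = th or KaneThresholds()
    if hit.probe_len <= 0:
        raise ValueError("probe_len must be positive")
    count_arm = (
        hit.matches >= th.min_matches
        and hit.matches / hit.probe_len >= th.min_identity_fraction
    )
    run_arm = hit.max_run >= th.min_contiguous_run
    return count_arm or run_arm


def find_intended_hit(
    probe: ProbeRecord, hits: Sequence[GenomeHit]
) -> GenomeHit | None:
    """The hit standing for the probe's design locus.

    If the probe declares a design locus, the best-scoring hit overlapping it
    is intended.  Otherwise the best-scoring exonic_single hit is taken (a
    documented choice; callers can inspect ties themselves).
    """
    if probe.intended_target is not None:
        t = probe.intended_target
        candidates = [
            h
            for h in hits
            if h.chrom == t.chrom and h.start < t.end and t.start < h.end
        ]
    else:
        candidates = [h for h in hits if h.region_class == "exonic_single"]
    if not candidates:
        return None
    return max(
        candidates, key=lambda h: (h.matches, h.max_run, -h.start, h.chrom)
    )


def cross_hyb_filter(
    probe: ProbeRecord,
    hits: Sequence[GenomeHit],
    th: KaneThresholds | None = None,
    duplex_dgs: Sequence[float] | None = None,
    dg_max: float = -15.0,
) -> tuple[bool, list[GenomeHit]]:
    """Flag probes with signal-producing secondary targets.

    A secondary hit contributes mixed signal only if it satisfies the Kane
    criteria, lies in an expressed region, and its heteroduplex is stable
    (duplex dG <= dg_max).  ``duplex_dgs`` aligns with ``hits``; if omitted,
    any Kane-qualifying expressed hit counts (duplex stability not screened).
    Returns the decision and the contributing hits for the ledger.  With no
    identifiable intended hit the decision defers to the loss-of-target
    filter and nothing is flagged here.
    """
    th = th or KaneThresholds()
    if duplex_dgs is not None and len(duplex_dgs) != len(hits):
        raise ValueError("duplex_dgs must align with hits")
    intended = find_intended_hit(probe, hits)
    if intended is None:
        return False, []
    contributing = []
    for idx, h in enumerate(hits):
        if h.key == intended.key:
            continue
        if not kane_flag(h, th):
            continue
        if not h.expressed:
            continue
        if duplex_dgs is not None and duplex_dgs[idx] > dg_max:
            continue
        contributing.append(h)
    return bool(contributing), contributing


def loss_of_target_flag(probe: ProbeRecord, hits: Sequence[GenomeHit]) -> bool:
    """True if the probe lost its target: no intended hit, or the intended
    hit violates the single-exon design contract (e.g. crosses a junction)."""
    intended = find_intended_hit(probe, hits)
    if intended is None:
        return True
    return intended.region_class != "exonic_single"


def snp_flag(
    probe: ProbeRecord,
    intended_hit: GenomeHit,
    ann: AnnotationSet,
    max_snps: int = DEFAULT_MAX_SNPS,
) -> tuple[bool, int, list[SnpRecord]]:
    """Count variant sites under the intended hit and flag at >= max_snps.

    A multi-allelic site counts once; indels count as one site each.  Probes
    with 1 to max_snps-1 sites are not flagged but the per-SNP records are
    returned so they can be emitted to the low-SNP annotation report.
    """
    overlapping = [
        s
        for s in ann.snps
        if s.chrom == intended_hit.chrom and intended_hit.start <= s.pos < intended_hit.end
    ]
    # one site per position: alternate alleles at the same position collapse
    by_pos: dict[int, SnpRecord] = {}
    for s in overlapping:
        by_pos.setdefault(s.pos, s)
    records = [by_pos[p] for p in sorted(by_pos)]
    count = len(records)
    return count >= max_snps, count, records


_POLYG_CACHE: dict[int, re.Pattern] = {}


def polyg_flag(sequence: str, min_run: int = DEFAULT_POLYG_MIN_RUN) -> bool:
    """True iff the sequence contains >= min_run consecutive guanines."""
    pat = _POLYG_CACHE.get(min_run)
    if pat is None:
        pat = re.compile("G{%d,}" % min_run)
        _POLYG_CACHE[min_run] = pat
    return pat.search(sequence) is not None


def repeat_flag(
    probe: ProbeRecord,
    repeats: Mapping[str, str],
    min_match: int = DEFAULT_REPEAT_MIN_MATCH,
) -> bool:
    """True iff the probe shares an exact substring of length >= min_match
    with any repeat-library entry, on either strand.

    A shared substring of length >= k exists iff one of length exactly k
    does, so membership of the probe's k-mers (forward and reverse
    complement) in each library sequence decides the flag.
    """
    seq = probe.sequence
    if len(seq) < min_match:
        return False
    kmers = {seq[i : i + min_match] for i in range(len(seq) - min_match + 1)}
    rc = revcomp(seq)
    kmers |= {rc[i : i + min_match] for i in range(len(rc) - min_match + 1)}
    for rseq in repeats.values():
        for i in range(len(rseq) - min_match + 1):
            if rseq[i : i + min_match] in kmers:
                return True
    return False


# ---------------------------------------------------------------------------
# verdict ledger
# ---------------------------------------------------------------------------


@dataclass
class FilterVerdict:
    """Per-probe ledger entry: raised flags, SNP count, add-back provenance.

    ``allowed`` is order-independent by construction (flags form a set) and
    reflects add-backs: a probe is allowed iff every raised flag has been
    explicitly cleared with a reason.
    """

    probe_id: str
    flags: set[str] = field(default_factory=set)
    snp_count: int = 0
    addback_log: list[tuple[str, str]] = field(default_factory=list)

    @property
    def effective_flags(self) -> set[str]:
        cleared = {flag for flag, _ in self.addback_log}
        return self.flags - cleared

    @property
    def allowed(self) -> bool:
        return not self.effective_flags

    def add_back(self, flag: str, reason: str) -> None:
        if flag not in FLAG_NAMES:
            raise ValueError(f"unknown flag {flag!r}")
        self.addback_log.append((flag, reason))


def assemble_verdicts(
    outcomes: Iterable[tuple[str, str, bool]],
    snp_counts: Mapping[str, int] | None = None,
) -> list[FilterVerdict]:
    """Merge per-filter outcomes into one ledger.

    ``outcomes`` yields (probe_id, flag_name, raised) triples.  Every probe
    must carry an outcome for every flag that appears at all (each enabled
    filter ran on each probe); duplicate consistent outcomes are idempotent,
    conflicting duplicates are an error.  The result is independent of input
    order: flags form a set union and the ledger is sorted by probe id.
    """
    seen: dict[tuple[str, str], bool] = {}
    for probe_id, flag, raised in outcomes:
        if flag not in FLAG_NAMES:
            raise ValueError(f"unknown flag {flag!r}")
        key = (probe_id, flag)
        if key in seen and seen[key] != bool(raised):
            raise ValueError(
                f"conflicting outcomes for probe {probe_id!r}, filter {flag!r}"
            )
        seen[key] = bool(raised)
    probes = sorted({p for p, _ in seen})
    enabled = {f for _, f in seen}
    missing = [
        (p, f) for p in probes for f in enabled if (p, f) not in seen
    ]
    if missing:
        raise ValueError(
            f"missing outcomes for {len(missing)} probe/filter pairs, "
            f"first: {missing[0]!r}"
        )
    snp_counts = snp_counts or {}
    return [
        FilterVerdict(
            probe_id=p,
            flags={f for f in enabled if seen[(p, f)]},
            snp_count=int(snp_counts.get(p, 0)),
        )
        for p in probes
    ]
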