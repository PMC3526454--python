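"""Probe-to-genome mapping and hit classification.

Expression-array probes are designed to sit inside a single exon of their
target transcript.  Whether a probe still honors that contract on the current
reference -- and whether it has near-identical secondary loci that could
contribute off-target signal -- is established here, either by an internal
deterministic seed-and-extend ungapped scanner (:func:`scan_hits`) or by
ingesting an external aligner's tabular output (:func:`ingest_hits`).
Each hit is then classified against exon and expressed-region annotations
(:func:`classify_hit`).

Coordinates are 0-based half-open on the forward genome strand throughout;
1-based inclusive inputs are converted on ingest.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGT")

DEFAULT_SEED_LEN = 12
DEFAULT_MIN_REPORT_MATCHES = 50


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Locus:
    """A genomic interval with strand, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"locus start must be < end, got [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class ProbeRecord:
    """One array probe: identity, 60-mer sequence, intended design locus."""

    probe_id: str
    sequence: str
    intended_target: Locus | None = None
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"probe {self.probe_id}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"probe {self.probe_id}: non-ACGT characters {sorted(bad)!r}"
            )


@dataclass(frozen=True)
class GenomeHit:
    """One ungapped alignment of a probe to the genome.

    ``matches`` counts identical aligned bases; ``max_run`` is the longest
    contiguous exact-match stretch; ``region_class`` and ``expressed`` are
    filled by :func:`classify_hit`.
    """

    probe_id: str
    chrom: str
    start: int
    end: int
    strand: str
    matches: int
    probe_len: int
    max_run: int
    region_class: str | None = None
    expressed: bool | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.matches <= self.probe_len):
            raise ValueError("matches must satisfy 0 <= matches <= probe_len")
        if not (0 <= self.max_run <= self.matches):
            raise ValueError("max_run must satisfy 0 <= max_run <= matches")
        if self.start >= self.end:
            raise ValueError("hit start must be < end")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Exon:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("exon start must be < end")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("interval start must be < end")


@dataclass(frozen=True)
class SnpRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    is_indel: bool = False


@dataclass
class AnnotationSet:
    """Exons, expressed regions, variant sites and a repeat-element library."""

    exons: list[Exon] = field(default_factory=list)
    expressed_regions: list[Interval] = field(default_factory=list)
    snps: list[SnpRecord] = field(default_factory=list)
    repeats: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------


class SeedIndex:
    """Exact k-mer index of a genome; seeds containing non-ACGT are skipped
    (masked bases can never anchor a hit)."""

    def __init__(self, genome: Mapping[str, str], seed_len: int):
        if seed_len < 8:
            raise ValueError("seed_len must be >= 8")
        if not genome:
            raise ValueError("genome is empty")
        self.seed_len = seed_len
        self.genome = dict(genome)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for off in range(len(seq) - seed_len + 1):
                kmer = seq[off : off + seed_len]
                if set(kmer) <= _VALID:
                    self._index.setdefault(kmer, []).append((chrom, off))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _window_stats(query: str, window: str) -> tuple[int, int]:
    matches = 0
    run = 0
    max_run = 0
    for a, b in zip(query, window):
        if a == b and a in _VALID:
            matches += 1
            run += 1
            if run > max_run:
                max_run = run
        else:
            run = 0
    return matches, max_run


def scan_hits(
    probe: ProbeRecord,
    genome: Mapping[str, str],
    seed_len: int = DEFAULT_SEED_LEN,
    min_report_matches: int = DEFAULT_MIN_REPORT_MATCHES,
    index: SeedIndex | None = None,
) -> list[GenomeHit]:
    """All seed-anchored ungapped placements with >= min_report_matches.

    Both strands are scanned: a minus-strand hit means the reverse complement
    of the probe matches the forward genome at that interval.  Complete for
    every placement whose longest exact run is at least ``seed_len``.
    Deterministic: hits sorted by (chrom, start, strand).
    """
    if index is None:
        index = SeedIndex(genome, seed_len)
    elif index.seed_len != seed_len:
        raise ValueError("index seed length does not match seed_len")
    L = len(probe.sequence)
    hits: list[GenomeHit] = []
    seen: set[tuple[str, int, str]] = set()
    for strand, query in (("+", probe.sequence), ("-", revcomp(probe.sequence))):
        for q in range(0, L - seed_len + 1):
            for chrom, g in index.lookup(query[q : q + seed_len]):
                start = g - q
                if start < 0 or start + L > len(index.genome[chrom]):
                    continue
                if (chrom, start, strand) in seen:
                    continue
                seen.add((chrom, start, strand))
                window = index.genome[chrom][start : start + L]
                matches, max_run = _window_stats(query, window)
                if matches >= min_report_matches:
                    hits.append(
                        GenomeHit(
                            probe_id=probe.probe_id,
                            chrom=chrom,
                            start=start,
                            end=start + L,
                            strand=strand,
                            matches=matches,
                            probe_len=L,
                            max_run=max_run,
                        )
                    )
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


def scan_all(
    probes: Iterable[ProbeRecord],
    genome: Mapping[str, str],
    seed_len: int = DEFAULT_SEED_LEN,
    min_report_matches: int = DEFAULT_MIN_REPORT_MATCHES,
) -> dict[str, list[GenomeHit]]:
    """Scan many probes against one genome, sharing a single seed index."""
    index = SeedIndex(genome, seed_len)
    return {
        p.probe_id: scan_hits(p, genome, seed_len, min_report_matches, index=index)
        for p in probes
    }


# ---------------------------------------------------------------------------
# ingestion of external aligner tables
# ---------------------------------------------------------------------------

_BLAST6_COLS = 12


def ingest_hits(path, one_based: bool = True) -> list[GenomeHit]:
    """Convert a 12-column tab-separated alignment table into GenomeHits.

    Expected columns (BLAST tabular layout): query id, subject id, percent
    identity, alignment length, mismatches, gap opens, qstart, qend, sstart,
    send, e-value, bit score.  Subject coordinates are 1-based inclusive
    unless ``one_based=False``; minus-strand alignments are declared by
    sstart > send.  Percent identity is converted to an integer match count
    by rounding half up; the table does not carry the longest contiguous run,
    which is reconstructed as the pigeonhole lower bound
    ceil(matches / (mismatches + 1)).
    """
    hits: list[GenomeHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < _BLAST6_COLS:
                raise ValueError(
                    f"{path}: row {lineno}: expected {_BLAST6_COLS} columns, "
                    f"got {len(parts)}"
                )
            try:
                qid, sid = parts[0], parts[1]
                pident = float(parts[2])
                length = int(parts[3])
                mismatches = int(parts[4])
                gapopen = int(parts[5])
                sstart, send = int(parts[8]), int(parts[9])
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: malformed field ({exc})")
            matches = math.floor(pident / 100.0 * length + 0.5)
            strand = "+" if sstart <= send else "-"
            lo, hi = min(sstart, send), max(sstart, send)
            start = lo - 1 if one_based else lo
            end = hi if one_based else hi
            if matches == 0:
                max_run = 0
            elif mismatches == 0 and gapopen == 0:
                max_run = length
            else:
                max_run = min(matches, math.ceil(matches / (mismatches + 1)))
            hits.append(
                GenomeHit(
                    probe_id=qid,
                    chrom=sid,
                    start=start,
                    end=end,
                    strand=strand,
                    matches=min(matches, length),
                    probe_len=length,
                    max_run=max_run,
                )
            )
    return hits


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_hit(hit: GenomeHit, ann: AnnotationSet) -> GenomeHit:
    """Fill region_class and expressed; pure in the annotation contents.

    exonic_single: the hit interval is fully contained in one exon.
    exon_junction: it overlaps an exon but is not contained (crosses a
    boundary or spans two exons).  Otherwise intronic when inside the span of
    some gene's exons, intergenic when not.  ``expressed`` is a one-base
    overlap test against the expressed-region intervals.
    """
    chrom_known = any(e.chrom == hit.chrom for e in ann.exons) or any(
        r.chrom == hit.chrom for r in ann.expressed_regions
    )
    exons = [e for e in ann.exons if e.chrom == hit.chrom]
    contained = any(e.start <= hit.start and hit.end <= e.end for e in exons)
    overlapping = [e for e in exons if e.start < hit.end and hit.start < e.end]
    if contained:
        region = "exonic_single"
    elif overlapping:
        region = "exon_junction"
    else:
        gene_spans: dict[str, tuple[int, int]] = {}
        for e in exons:
            lo, hi = gene_spans.get(e.gene_id, (e.start, e.end))
            gene_spans[e.gene_id] = (min(lo, e.start), max(hi, e.end))
        if any(lo < hit.end and hit.start < hi for lo, hi in gene_spans.values()):
            region = "intronic"
        else:
            region = "intergenic"
            if not chrom_known:
                logger.warning(
                    "hit %s on unknown chromosome %r classified intergenic",
                    hit.probe_id,
                    hit.chrom,
                )
    expressed = any(
        r.chrom == hit.chrom and r.start < hit.end and hit.start < r.end
        for r in ann.expressed_regions
    )
    return replace(hit, region_class=region, expressed=expressed)


def hit_target_sequence(hit: GenomeHit, genome: Mapping[str, str]) -> str:
    """The strand a probe would hybridize to at this hit.

    A plus-strand hit means the probe matches the forward genome, so its
    hybridization partner is the reverse complement of that window; a
    minus-strand hit binds the forward window itself.
    """
    window = genome[hit.chrom][hit.start : hit.end]
    return revcomp(window) if hit.strand == "+" else window


def classify_all(
    hits: Mapping[str, Sequence[GenomeHit]], ann: AnnotationSet
) -> dict[str, list[GenomeHit]]:
    return {pid: [classify_hit(h, ann) for h in hs] for pid, hs in hits.items()}
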