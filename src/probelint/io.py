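"""Readers and writers for the on-disk formats, plus pipeline configuration.

All primary outputs are headered CSV/TSV so every stage's result is an
inspectable flat file.  Sequences travel as FASTA, expressed regions as
BED6, exons as GFF3 (converted to the internal 0-based half-open convention
on read), variant sites as a simple tab-separated table.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_map import AnnotationSet, Exon, Interval, Locus, ProbeRecord, SnpRecord
from .measurement_qc import IntensityMatrix
from .probe_filters import FLAG_NAMES, FilterVerdict

logger = logging.getLogger(__name__)


class InputError(Exception):
    """Malformed or missing user input (CLI exit code 2)."""


class ContractError(Exception):
    """A pipeline contract was violated (CLI exit code 3)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Every tunable threshold, with its published default.

    Round-trips losslessly through YAML (`to_yaml`/`from_yaml`).
    """

    kane_min_matches: int = 50
    kane_min_identity_fraction: float = 0.85
    kane_min_contiguous_run: int = 15
    max_snps: int = 4
    polyg_min_run: int = 4
    monomer_dg_cutoff: float = -5.2  # kcal/mol, probe removal (strict <)
    background_dg_cutoff: float = -10.0  # kcal/mol, background candidates
    duplex_dg_max: float = -15.0  # kcal/mol, cross-hyb duplex stability
    repeat_min_match: int = 15
    seed_len: int = 12
    min_report_matches: int = 50
    temperature: float = 60.0  # Celsius
    sodium: float = 1.0  # molar
    magnesium: float = 0.0  # molar
    outlier_k: float = 2.0
    alpha: float = 0.05
    correction: str = "bh_fdr"
    background_method: str = "stable_unexpressed_mean"
    measurement_filter_mode: str = "both"
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# sequence formats
# ---------------------------------------------------------------------------


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_probes(probes: Iterable[ProbeRecord], path) -> None:
    """Probes as FASTA; the design locus and gene ride in the description."""
    records = []
    for p in probes:
        desc = ""
        if p.intended_target is not None:
            t = p.intended_target
            desc = f"locus={t.chrom}:{t.start}-{t.end}({t.strand})"
        if p.gene_id:
            desc = (desc + " " if desc else "") + f"gene={p.gene_id}"
        records.append(SeqRecord(Seq(p.sequence), id=p.probe_id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_probes(path) -> list[ProbeRecord]:
    probes = []
    for r in SeqIO.parse(str(path), "fasta"):
        locus = None
        gene = None
        for token in r.description.split()[1:]:
            if token.startswith("locus="):
                region, strand = token[6:-1].split("("), token[-2]
                chrom, span = region[0].split(":")
                start, end = span.split("-")
                locus = Locus(chrom, int(start), int(end), strand)
            elif token.startswith("gene="):
                gene = token[5:]
        probes.append(
            ProbeRecord(
                probe_id=r.id,
                sequence=str(r.seq).upper(),
                intended_target=locus,
                gene_id=gene,
            )
        )
    return probes


# ---------------------------------------------------------------------------
# annotation formats
# ---------------------------------------------------------------------------


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tregion{i}\t0\t+\n")


def read_bed(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append(Interval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_gff3(exons: Iterable[Exon], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for e in exons:
            fh.write(
                f"{e.chrom}\tprobelint\texon\t{e.start + 1}\t{e.end}\t.\t"
                f"{e.strand}\t.\tgene_id={e.gene_id}\n"
            )


def read_gff3(path) -> list[Exon]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise InputError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            if parts[2] != "exon":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene = attrs.get("gene_id") or attrs.get("Parent") or attrs.get("ID", "")
            out.append(
                Exon(parts[0], int(parts[3]) - 1, int(parts[4]), parts[6], gene)
            )
    return out


def write_snp_table(snps: Iterable[SnpRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talts\tis_indel\n")
        for s in snps:
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref}\t{','.join(s.alts)}\t{int(s.is_indel)}\n"
            )


def read_snp_table(path) -> list[SnpRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, row in frame.iterrows():
        out.append(
            SnpRecord(
                chrom=row["chrom"],
                pos=int(row["pos"]),
                ref=row["ref"],
                alts=tuple(str(row["alts"]).split(",")),
                is_indel=bool(int(row["is_indel"])),
            )
        )
    return out


def write_annotations(ann: AnnotationSet, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    paths = {
        "exons": out_dir / "exons.gff3",
        "expressed": out_dir / "expressed.bed",
        "snps": out_dir / "snps.tsv",
        "repeats": out_dir / "repeats.fasta",
    }
    write_gff3(ann.exons, paths["exons"])
    write_bed(ann.expressed_regions, paths["expressed"])
    write_snp_table(ann.snps, paths["snps"])
    write_fasta(ann.repeats, paths["repeats"])
    return paths


def read_annotations(out_dir) -> AnnotationSet:
    out_dir = Path(out_dir)
    return AnnotationSet(
        exons=read_gff3(out_dir / "exons.gff3"),
        expressed_regions=read_bed(out_dir / "expressed.bed"),
        snps=read_snp_table(out_dir / "snps.tsv"),
        repeats=read_fasta(out_dir / "repeats.fasta"),
    )


# ---------------------------------------------------------------------------
# intensity tables
# ---------------------------------------------------------------------------

_CLASS_ROW = "#class"
_CHANNEL_ROW = "#channel"


def write_intensity_table(matrix: IntensityMatrix, path) -> None:
    """TSV: header of sample ids, then class/channel annotation rows, then
    one probe per row."""
    with open(path, "w") as fh:
        cols = matrix.sample_ids
        fh.write("probe_id\t" + "\t".join(cols) + "\n")
        fh.write(
            _CLASS_ROW + "\t" + "\t".join(matrix.class_of[c] for c in cols) + "\n"
        )
        fh.write(
            _CHANNEL_ROW
            + "\t"
            + "\t".join(matrix.channel_of[c] for c in cols)
            + "\n"
        )
        for probe in matrix.values.index:
            row = matrix.values.loc[probe]
            fh.write(
                probe
                + "\t"
                + "\t".join("" if pd.isna(v) else repr(float(v)) for v in row)
                + "\n"
            )


def parse_intensity_table(path, dialect: str = "log10") -> IntensityMatrix:
    """Read an intensity TSV; ``dialect='raw'`` log10-transforms and drops
    negative or missing raw values (counted in the log)."""
    if dialect not in ("log10", "raw"):
        raise InputError(f"unknown intensity dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if _CLASS_ROW not in frame.index:
        raise InputError(f"{path}: missing {_CLASS_ROW} annotation row")
    class_of = frame.loc[_CLASS_ROW]
    if _CHANNEL_ROW in frame.index:
        channel_of = frame.loc[_CHANNEL_ROW]
    else:
        channel_of = pd.Series("sample_channel", index=frame.columns)
    data = frame.drop(index=[r for r in (_CLASS_ROW, _CHANNEL_ROW) if r in frame.index])
    dupes = data.index[data.index.duplicated()].unique().tolist()
    if dupes:
        raise InputError(f"{path}: duplicate probe ids: {dupes}")
    values = data.apply(pd.to_numeric, errors="coerce").astype(float)
    values.index.name = None
    if dialect == "raw":
        raw = values.to_numpy()
        bad = np.isnan(raw) | (raw <= 0)
        n_dropped = int(bad.sum())
        if n_dropped:
            logger.info(
                "%s: dropped %d negative/missing raw measurements", path, n_dropped
            )
        raw = np.where(bad, np.nan, raw)
        values = pd.DataFrame(
            np.log10(raw), index=values.index, columns=values.columns
        )
    return IntensityMatrix(
        values=values, class_of=class_of.copy(), channel_of=channel_of.copy()
    )


# ---------------------------------------------------------------------------
# verdict ledger
# ---------------------------------------------------------------------------


def write_verdict_ledger(verdicts: Sequence[FilterVerdict], path) -> None:
    """Ledger CSV with stable column order; add-backs serialize as
    'flag:reason' items separated by '|'."""
    rows = []
    for v in verdicts:
        row = {"probe_id": v.probe_id}
        for f in FLAG_NAMES:
            row[f] = f in v.flags
        row["snp_count"] = v.snp_count
        row["allowed"] = v.allowed
        row["addbacks"] = "|".join(f"{f}:{r}" for f, r in v.addback_log)
        rows.append(row)
    cols = ["probe_id", *FLAG_NAMES, "snp_count", "allowed", "addbacks"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_verdict_ledger(path) -> list[FilterVerdict]:
    frame = pd.read_csv(path, dtype={"probe_id": str, "addbacks": str})
    out = []
    for _, row in frame.iterrows():
        v = FilterVerdict(
            probe_id=row["probe_id"],
            flags={f for f in FLAG_NAMES if bool(row[f])},
            snp_count=int(row["snp_count"]),
        )
        if isinstance(row.get("addbacks"), str) and row["addbacks"]:
            for item in row["addbacks"].split("|"):
                flag, _, reason = item.partition(":")
                v.add_back(flag, reason)
        out.append(v)
    return out


def verdict_summary(verdicts: Sequence[FilterVerdict]) -> pd.DataFrame:
    """Per-filter counts and percentages plus the union, ledger side report."""
    n = len(verdicts)
    rows = []
    for f in FLAG_NAMES:
        c = sum(1 for v in verdicts if f in v.flags)
        rows.append({"filter": f, "flagged": c, "percent": 100.0 * c / n if n else 0.0})
    dep = sum(1 for v in verdicts if not v.allowed)
    rows.append(
        {"filter": "any", "flagged": dep, "percent": 100.0 * dep / n if n else 0.0}
    )
    return pd.DataFrame(rows, columns=["filter", "flagged", "percent"])
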