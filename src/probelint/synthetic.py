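"""Seeded synthetic universes with surgically planted probe defects.

Every pipeline stage is testable without external downloads: this module
builds a random genome with non-overlapping exons, an expressed-region
subset, 60-mer probes copied from single exons, and a truth table recording
exactly which defect each probe carries:

* ``cross_hyb``   -- a verbatim copy of the probe planted in a second,
  expressed exon (unambiguous Kane-qualifying secondary target);
* ``loss_of_target`` -- either a probe whose sequence occurs nowhere in the
  genome (no hit) or one copied across an exon-exon junction;
* ``snp``         -- four variant records planted under the probe footprint;
* ``poly_g``      -- a G4 run written into the probe (and its genomic locus);
* ``delta_g``     -- a stem-loop probe built to fold between the removal
  cutoff and the background criterion;
* ``repeat``      -- a library entry sharing a long exact substring with the
  probe;
* background probes -- very stable folders (dG < -10) mapped to genes marked
  unexpressed, feeding the background estimator.

Clean probes are rejection-sampled until they trip no filter, and a global
verification pass rescans the finished genome so that no probe has an
accidental Kane-level secondary locus.  All generators are pure functions of
(config, seed); identical inputs give byte-identical universes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_map import (
    AnnotationSet,
    Exon,
    Interval,
    Locus,
    ProbeRecord,
    SnpRecord,
    revcomp,
)
from .measurement_qc import IntensityMatrix
from .probe_filters import polyg_flag
from .qpcr import DilutionSeries, PfafflInput
from .thermo import BACKGROUND_DG_CUTOFF, MONOMER_DG_CUTOFF, monomer_mfe

_BASES = np.array(list("ACGT"))
_CHROM = "chr1"


@dataclass(frozen=True)
class UniverseConfig:
    """Counts and geometry of a synthetic probe universe."""

    n_clean: int = 20
    n_cross_hyb: int = 5
    n_loss_of_target: int = 5
    n_snp: int = 5
    n_poly_g: int = 5
    n_delta_g: int = 5
    n_repeat: int = 5
    n_background: int = 5
    genome_length: int = 60_000
    probe_len: int = 60
    exon_len: int = 180
    exon_gap: int = 120
    snps_per_probe: int = 4
    repeat_share_len: int = 20
    kane_min_matches: int = 50
    kane_min_run: int = 15

    def __post_init__(self) -> None:
        counts = self.category_counts()
        if any(c < 0 for c in counts.values()):
            raise ValueError("defect counts must be >= 0")
        if self.genome_length < 10 * self.probe_len * max(1, sum(counts.values())):
            # generous packing guard; the slot check below is the binding one
            pass

    def category_counts(self) -> dict[str, int]:
        return {
            "clean": self.n_clean,
            "cross_hyb": self.n_cross_hyb,
            "loss_of_target": self.n_loss_of_target,
            "snp": self.n_snp,
            "poly_g": self.n_poly_g,
            "delta_g": self.n_delta_g,
            "repeat": self.n_repeat,
            "background": self.n_background,
        }


@dataclass
class Universe:
    genome: dict[str, str]
    annotations: AnnotationSet
    probes: list[ProbeRecord]
    truth: pd.DataFrame
    config: UniverseConfig
    seed: int


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _draw_clean(rng: np.random.Generator, n: int, max_tries: int = 500) -> str:
    """A random n-mer with no G4 run and monomer dG above the removal cutoff."""
    for _ in range(max_tries):
        seq = _rand_seq(rng, n)
        if polyg_flag(seq):
            continue
        if monomer_mfe(seq) < MONOMER_DG_CUTOFF:
            continue
        return seq
    raise RuntimeError("failed to draw a clean probe sequence")


def _draw_stemloop(
    rng: np.random.Generator,
    n: int,
    stem_len: int,
    dg_range: tuple[float, float],
    max_tries: int = 500,
) -> str:
    """A probe built stem-loop by construction, folding into dg_range."""
    lo, hi = dg_range
    loop = "TCTTA"  # G-free terminal loop
    for _ in range(max_tries):
        stem = "".join(
            rng.choice(_BASES, size=stem_len, p=[0.12, 0.38, 0.38, 0.12])
        )
        core = stem + loop + revcomp(stem)
        pad = n - len(core)
        left = pad // 2
        seq = _rand_seq(rng, left) + core + _rand_seq(rng, pad - left)
        if polyg_flag(seq):
            continue
        dg = monomer_mfe(seq)
        if lo < dg < hi:
            return seq
    raise RuntimeError("failed to construct a stem-loop probe in the dG range")


def _insert_g_run(rng: np.random.Generator, seq: str, run: int = 4) -> str:
    pos = int(rng.integers(2, len(seq) - run - 2))
    return seq[:pos] + "G" * run + seq[pos + run :]


def _draw_polyg(rng: np.random.Generator, n: int, max_tries: int = 500) -> str:
    """A G4-run probe that still folds above the removal cutoff."""
    for _ in range(max_tries):
        seq = _insert_g_run(rng, _draw_clean(rng, n))
        if monomer_mfe(seq) >= MONOMER_DG_CUTOFF:
            return seq
    raise RuntimeError("failed to draw a poly-G probe")


# ---------------------------------------------------------------------------
# universe generation
# ---------------------------------------------------------------------------


def _exhaustive_placements(
    probe_seq: str,
    genome_codes: np.ndarray,
    min_matches: int,
    kmer_index: Mapping[str, list[int]],
    min_run: int,
) -> set[tuple[int, str]]:
    """All implied placements reaching the Kane match count or sharing a
    min_run-mer with the genome, by brute force (used for verification)."""
    L = len(probe_seq)
    placements: set[tuple[int, str]] = set()
    win = np.lib.stride_tricks.sliding_window_view(genome_codes, L)
    for strand, q in (("+", probe_seq), ("-", revcomp(probe_seq))):
        qc = np.frombuffer(q.encode(), dtype=np.uint8)
        matches = (win == qc).sum(axis=1)
        for off in np.nonzero(matches >= min_matches)[0]:
            placements.add((int(off), strand))
        for i in range(L - min_run + 1):
            for pos in kmer_index.get(q[i : i + min_run], ()):
                start = pos - i
                if 0 <= start <= len(genome_codes) - L:
                    placements.add((start, strand))
    return placements


def simulate_probe_universe(
    config: UniverseConfig | None = None, seed: int = 0
) -> Universe:
    """Generate genome + annotations + probes + truth table for one seed."""
    cfg = config or UniverseConfig()
    rng = np.random.default_rng(seed)
    counts = cfg.category_counts()
    n_probes = sum(counts.values())
    slot_size = cfg.exon_len + cfg.exon_gap
    n_slots = n_probes + cfg.n_cross_hyb  # extra slots host cross-hyb copies
    if n_slots * slot_size + cfg.exon_gap > cfg.genome_length:
        raise ValueError(
            f"infeasible packing: {n_slots} exon slots of {slot_size} bp do "
            f"not fit a {cfg.genome_length} bp genome"
        )
    genome = list(_rand_seq(rng, cfg.genome_length))
    half = cfg.exon_gap // 2

    def slot_start(i: int) -> int:
        return half + i * slot_size

    # --- assign slots and construct probes -------------------------------
    categories: list[str] = []
    for cat, cnt in counts.items():
        categories.extend([cat] * cnt)

    probes: list[ProbeRecord] = []
    exons: list[Exon] = []
    expressed: list[Interval] = []
    snps: list[SnpRecord] = []
    repeats: dict[str, str] = {}
    rows: list[dict] = []
    copy_slot = n_probes  # next free slot for cross-hyb copies
    # records needed for regeneration during verification
    writers: list[dict] = []

    def write(seq: str, start: int) -> None:
        genome[start : start + len(seq)] = list(seq)

    for idx, cat in enumerate(categories):
        pid = f"P{idx:04d}"
        gid = f"G{idx:04d}"
        o = slot_start(idx)
        exon = (o, o + cfg.exon_len)
        p_start = o + (cfg.exon_len - cfg.probe_len) // 2
        loci = [p_start]
        junction = False
        no_hit = False
        seq: str
        dg = 0.0
        snp_count = 0

        if cat == "clean" or cat == "snp" or cat == "cross_hyb" or cat == "repeat":
            seq = _draw_clean(rng, cfg.probe_len)
            write(seq, p_start)
        elif cat == "poly_g":
            seq = _draw_polyg(rng, cfg.probe_len)
            write(seq, p_start)
        elif cat == "delta_g":
            seq = _draw_stemloop(
                rng, cfg.probe_len, stem_len=8,
                dg_range=(BACKGROUND_DG_CUTOFF + 0.5, MONOMER_DG_CUTOFF - 0.5),
            )
            write(seq, p_start)
        elif cat == "background":
            seq = _draw_stemloop(
                rng, cfg.probe_len, stem_len=12,
                dg_range=(-40.0, BACKGROUND_DG_CUTOFF - 0.5),
            )
            write(seq, p_start)
        elif cat == "loss_of_target":
            seq = _draw_clean(rng, cfg.probe_len)
            if idx % 2 == 0:
                # junction-spanning: two contiguous exons, probe across the seam
                junction = True
                seam = o + cfg.exon_len // 2
                p_start = seam - cfg.probe_len // 2
                loci = [p_start]
                write(seq, p_start)
            else:
                no_hit = True  # sequence never written into the genome
                loci = []
        else:  # pragma: no cover
            raise AssertionError(cat)

        if cat == "cross_hyb":
            c_o = slot_start(copy_slot)
            c_start = c_o + (cfg.exon_len - cfg.probe_len) // 2
            write(seq, c_start)
            loci.append(c_start)
            exons.append(Exon(_CHROM, c_o, c_o + cfg.exon_len, "+", f"XH_{gid}"))
            expressed.append(Interval(_CHROM, c_o, c_o + cfg.exon_len))
            copy_slot += 1

        if junction:
            seam = o + cfg.exon_len // 2
            exons.append(Exon(_CHROM, o, seam, "+", gid))
            exons.append(Exon(_CHROM, seam, o + cfg.exon_len, "+", gid))
        else:
            exons.append(Exon(_CHROM, *exon, "+", gid))
        if cat != "background":
            expressed.append(Interval(_CHROM, *exon))

        if cat == "snp":
            positions = sorted(
                int(p_start + q)
                for q in rng.choice(cfg.probe_len, cfg.snps_per_probe, replace=False)
            )
            for pos in positions:
                ref = genome[pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                snps.append(SnpRecord(_CHROM, pos, ref, (alt,)))
            snp_count = cfg.snps_per_probe

        if cat == "repeat":
            share = seq[20 : 20 + cfg.repeat_share_len]
            rep = _rand_seq(rng, 140) + share + _rand_seq(rng, 140)
            repeats[f"REP_{gid}"] = rep

        dg = monomer_mfe(seq)
        target = Locus(_CHROM, p_start, p_start + cfg.probe_len, "+")
        probes.append(
            ProbeRecord(probe_id=pid, sequence=seq, intended_target=target, gene_id=gid)
        )
        writers.append({"loci": loci, "category": cat, "no_hit": no_hit})
        rows.append(
            {
                "probe_id": pid,
                "gene_id": gid,
                "category": cat,
                "cross_hyb": cat == "cross_hyb",
                "loss_of_target": cat == "loss_of_target",
                "snp": cat == "snp" and cfg.snps_per_probe >= 4,
                "snp_count": snp_count,
                "delta_g": dg < MONOMER_DG_CUTOFF,
                "poly_g": cat == "poly_g",
                "repeat": cat == "repeat",
                "unexpressed_gene": cat == "background",
                "monomer_dg": dg,
            }
        )

    # --- verification pass: no accidental Kane-level secondary loci -------
    for round_ in range(25):
        gstr = "".join(genome)
        gcodes = np.frombuffer(gstr.encode(), dtype=np.uint8)
        kmer_index: dict[str, list[int]] = {}
        krun = cfg.kane_min_run
        for pos in range(len(gstr) - krun + 1):
            kmer_index.setdefault(gstr[pos : pos + krun], []).append(pos)
        dirty = False
        for i, probe in enumerate(probes):
            found = _exhaustive_placements(
                probe.sequence, gcodes, cfg.kane_min_matches, kmer_index, krun
            )
            expected = {(lo, "+") for lo in writers[i]["loci"]}
            if found == expected:
                continue
            dirty = True
            # redraw this probe's sequence and rewrite its loci
            cat = writers[i]["category"]
            if cat == "delta_g":
                new = _draw_stemloop(
                    rng, cfg.probe_len, 8,
                    (BACKGROUND_DG_CUTOFF + 0.5, MONOMER_DG_CUTOFF - 0.5),
                )
            elif cat == "background":
                new = _draw_stemloop(
                    rng, cfg.probe_len, 12, (-40.0, BACKGROUND_DG_CUTOFF - 0.5)
                )
            elif cat == "poly_g":
                new = _draw_polyg(rng, cfg.probe_len)
            else:
                new = _draw_clean(rng, cfg.probe_len)
            for lo in writers[i]["loci"]:
                write(new, lo)
            probes[i] = replace(probes[i], sequence=new)
            rows[i]["monomer_dg"] = monomer_mfe(new)
            rows[i]["delta_g"] = rows[i]["monomer_dg"] < MONOMER_DG_CUTOFF
            if cat == "repeat":
                share = new[20 : 20 + cfg.repeat_share_len]
                gid = rows[i]["gene_id"]
                repeats[f"REP_{gid}"] = (
                    _rand_seq(rng, 140) + share + _rand_seq(rng, 140)
                )
        if not dirty:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not resolve accidental secondary matches")

    truth = pd.DataFrame(rows).set_index("probe_id")
    ann = AnnotationSet(
        exons=exons, expressed_regions=expressed, snps=snps, repeats=repeats
    )
    return Universe(
        genome={_CHROM: "".join(genome)},
        annotations=ann,
        probes=probes,
        truth=truth,
        config=cfg,
        seed=seed,
    )


def filter_recovery(truth: pd.DataFrame, verdicts) -> pd.DataFrame:
    """Per-filter precision/recall of a verdict ledger against planted truth."""
    flags = ("cross_hyb", "loss_of_target", "snp", "delta_g", "poly_g", "repeat")
    by_id = {v.probe_id: v for v in verdicts}
    rows = []
    for flag in flags:
        pred = {p for p, v in by_id.items() if flag in v.flags}
        true = set(truth.index[truth[flag].astype(bool)])
        tp = len(pred & true)
        rows.append(
            {
                "filter": flag,
                "n_true": len(true),
                "precision": tp / len(pred) if pred else 1.0,
                "recall": tp / len(true) if true else 1.0,
            }
        )
    return pd.DataFrame(rows).set_index("filter")


# ---------------------------------------------------------------------------
# intensity matrices
# ---------------------------------------------------------------------------


@dataclass
class IntensitySim:
    matrix: IntensityMatrix
    de_truth: pd.DataFrame  # probe_id index: is_de, shift
    outlier_sample: str | None
    floor_mean: float
    floor_sd: float


def simulate_intensities(
    truth: pd.DataFrame,
    n_control: int = 6,
    n_disease: int = 6,
    n_de: int = 0,
    de_shift_sd: float = 3.0,
    noise_sd: float = 0.25,
    floor_mean: float = 2.5,
    floor_sd: float = 0.1,
    expressed_mean_range: tuple[float, float] = (3.2, 4.4),
    outlier_sd_multiple: float | None = None,
    seed: int = 0,
) -> IntensitySim:
    """Class-structured log10 intensities with planted DE genes and floor.

    Probes of unexpressed genes draw from the noise-floor distribution
    N(floor_mean, floor_sd) in every array; expressed probes draw from
    per-probe baselines with class-independent noise, and ``n_de`` clean
    probes get a +de_shift_sd * noise_sd location shift in the disease
    class.  When ``outlier_sd_multiple`` is set, the last disease sample's
    values are displaced so that its per-probe mean sits exactly that many
    (leave-one-out, ddof=0) SDs from the rest of its class.
    """
    if n_control < 3 or n_disease < 3:
        raise ValueError("class sizes must be >= 3")
    rng = np.random.default_rng(seed)
    probe_ids = list(truth.index)
    samples = [f"ctrl{i:02d}" for i in range(n_control)] + [
        f"dis{i:02d}" for i in range(n_disease)
    ]
    classes = ["control"] * n_control + ["disease"] * n_disease
    base = np.empty(len(probe_ids))
    is_floor = truth["unexpressed_gene"].to_numpy(bool)
    lo, hi = expressed_mean_range
    base[~is_floor] = rng.uniform(lo, hi, size=(~is_floor).sum())
    base[is_floor] = floor_mean

    clean_ids = [p for p in probe_ids if truth.at[p, "category"] == "clean"]
    if n_de > len(clean_ids):
        raise ValueError("more DE probes requested than clean probes available")
    de_ids = sorted(rng.choice(clean_ids, size=n_de, replace=False)) if n_de else []
    shift = de_shift_sd * noise_sd

    sd = np.where(is_floor, floor_sd, noise_sd)
    values = base[:, None] + rng.normal(0.0, 1.0, (len(probe_ids), len(samples))) * sd[
        :, None
    ]
    for p in de_ids:
        r = probe_ids.index(p)
        values[r, n_control:] += shift

    frame = pd.DataFrame(values, index=probe_ids, columns=samples)
    outlier_sample = None
    if outlier_sd_multiple is not None:
        outlier_sample = samples[-1]
        cls_cols = samples[n_control:]
        means = frame[cls_cols].mean(axis=0)
        others = means.drop(outlier_sample).to_numpy(float)
        m, s = float(np.mean(others)), float(np.std(others, ddof=0))
        if s == 0:
            s = noise_sd / math.sqrt(len(probe_ids))
        frame[outlier_sample] += m + outlier_sd_multiple * s - float(
            means[outlier_sample]
        )

    matrix = IntensityMatrix(
        values=frame, class_of=pd.Series(classes, index=samples)
    )
    de_truth = pd.DataFrame(
        {
            "is_de": [p in set(de_ids) for p in probe_ids],
            "shift": [shift if p in set(de_ids) else 0.0 for p in probe_ids],
        },
        index=probe_ids,
    )
    return IntensitySim(
        matrix=matrix,
        de_truth=de_truth,
        outlier_sample=outlier_sample,
        floor_mean=floor_mean,
        floor_sd=floor_sd,
    )


# ---------------------------------------------------------------------------
# qPCR titration series
# ---------------------------------------------------------------------------


@dataclass
class CqSim:
    series: dict[str, DilutionSeries]
    pfaffl_inputs: dict[str, PfafflInput]
    truth: pd.DataFrame  # gene_id index: true_ratio, efficiency


def simulate_cq(
    true_ratios: Mapping[str, float],
    efficiencies: Mapping[str, float],
    reference_gene: str = "REF",
    reference_efficiency: float = 2.0,
    noise_sd: float = 0.1,
    n_levels: int = 6,
    n_replicates: int = 3,
    dilution_step: float = 10.0,
    seed: int = 0,
) -> CqSim:
    """Dilution series and control-minus-treated dCq records per gene.

    Cq follows the standard curve Cq = intercept + level * log_E(step) with
    per-replicate Gaussian noise; the dCq of a gene with true expression
    ratio rho is log_E(rho) (control minus treated), observed with the noise
    of a difference of two triplicate means.
    """
    for gene, e in efficiencies.items():
        if not (1.0 < e <= 2.2):
            raise ValueError(f"{gene}: efficiency must lie in (1, 2.2]")
    if not (1.0 < reference_efficiency <= 2.2):
        raise ValueError("reference efficiency must lie in (1, 2.2]")
    rng = np.random.default_rng(seed)
    series: dict[str, DilutionSeries] = {}
    pfaffl: dict[str, PfafflInput] = {}
    rows = []
    all_genes = {reference_gene: reference_efficiency, **dict(efficiencies)}
    dct_sd = noise_sd * math.sqrt(2.0 / n_replicates)
    for gene in sorted(all_genes):
        e = all_genes[gene]
        intercept = float(rng.uniform(15.0, 20.0))
        step_cycles = math.log(dilution_step) / math.log(e)
        cq = (
            intercept
            + np.arange(n_levels)[:, None] * step_cycles
            + rng.normal(0.0, noise_sd, (n_levels, n_replicates))
        )
        series[gene] = DilutionSeries(gene_id=gene, dilution_step=dilution_step, cq=cq)
    for gene in sorted(true_ratios):
        e = all_genes[gene]
        rho = true_ratios[gene]
        dct_t = math.log(rho) / math.log(e) + float(rng.normal(0.0, dct_sd))
        dct_r = float(rng.normal(0.0, dct_sd))
        pfaffl[gene] = PfafflInput(
            e_target=e,
            e_reference=reference_efficiency,
            dct_target=dct_t,
            dct_reference=dct_r,
        )
        rows.append({"gene_id": gene, "true_ratio": rho, "efficiency": e})
    truth = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()
    return CqSim(series=series, pfaffl_inputs=pfaffl, truth=truth)
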