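"""Nearest-neighbor DNA thermodynamics for probe quality control.

Long oligonucleotide probes (60-mers) that fold back on themselves compete
with probe--target duplex formation: a probe whose most stable intramolecular
hairpin has a strongly negative free energy responds poorly to increasing
target concentration and is removed from analysis.  This module computes

* ``monomer_mfe`` -- the minimum free energy of a single-hairpin secondary
  structure (one terminal loop, interior loops and bulges allowed in the
  stem; no multiloops or pseudoknots), using the unified DNA nearest-neighbor
  stack table (dG = dH - T*dS per stack) with a logarithmic sodium
  correction and tabulated loop penalties;
* ``duplex_dg`` -- the free energy of the best ungapped probe/target
  heteroduplex over all alignment offsets, used to decide whether an
  off-target genomic hit is stable enough to contribute signal;
* ``delta_g_flag`` -- the retention rule: probes folding below the cutoff
  (default -5.2 kcal/mol) are removed.

A second, more stringent constant (``BACKGROUND_DG_CUTOFF`` = -10 kcal/mol)
marks "very stable" folders used to estimate the scanner background from
probes of unexpressed genes (see :mod:`probelint.measurement_qc`).

Units: kcal/mol throughout; temperatures in degrees Celsius at the API
boundary, Kelvin internally.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Mapping, Sequence

logger = logging.getLogger(__name__)

#: Removal cutoff for monomer folding stability, kcal/mol (strict <).
MONOMER_DG_CUTOFF = -5.2
#: "Very stable" monomer criterion used to select background-estimation
#: candidate probes, kcal/mol (strict <).
BACKGROUND_DG_CUTOFF = -10.0
#: Default duplex-stability ceiling for a cross-hybridizing secondary target
#: to be considered signal-producing, kcal/mol.
DUPLEX_DG_MAX = -15.0

R_KCAL = 1.987e-3  # gas constant, kcal/(mol*K)
T_REF = 310.15  # 37 C, the loop-table reference temperature, K
MIN_HAIRPIN_LOOP = 3
MAX_INTERIOR_LOOP = 30  # cap on total unpaired bases in interior/bulge loops

_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}
_VALID = frozenset("ACGT")


def _validate_seq(seq: str, *, what: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"empty {what}")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-ACGT characters in {what}: {sorted(bad)!r}")
    return seq


@dataclass(frozen=True)
class ThermoConditions:
    """Hybridization conditions for free-energy evaluation.

    The array chemistry operates between 55 and 62 C in 1.0 M Na+ with no
    magnesium; temperatures outside that window are accepted with a warning.
    """

    temperature: float = 60.0  # Celsius
    sodium: float = 1.0  # molar
    magnesium: float = 0.0  # molar

    def __post_init__(self) -> None:
        if self.sodium <= 0:
            raise ValueError("sodium concentration must be positive")
        if not (55.0 <= self.temperature <= 62.0):
            logger.warning(
                "temperature %.1f C is outside the validated 55-62 C window",
                self.temperature,
            )

    @property
    def kelvin(self) -> float:
        return self.temperature + 273.15


@dataclass
class ThermoProfile:
    """Per-probe thermodynamic summary; monomer_dg uses the convention that
    an unstructured probe scores 0 (never positive)."""

    probe_id: str
    monomer_dg: float
    duplex_dg: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.monomer_dg > 0:
            raise ValueError("monomer_dg must be <= 0 (unstructured = 0)")


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def _load_params() -> tuple[dict[str, tuple[float, float]], dict[str, dict[int, float]]]:
    stacks: dict[str, tuple[float, float]] = {}
    loops: dict[str, dict[int, float]] = {
        "hairpin_loop": {},
        "internal_loop": {},
        "bulge_loop": {},
    }
    text = resources.files("probelint").joinpath("data/nn_params.tsv").read_text()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("kind\t"):
            continue
        parts = line.split("\t")
        kind, key = parts[0], parts[1]
        if kind == "stack":
            stacks[key] = (float(parts[2]), float(parts[3]))
        else:
            loops[kind][int(key)] = float(parts[4])
    return stacks, loops


def stack_dg(dinuc: str, cond: ThermoConditions) -> float:
    """Free energy of one Watson-Crick stack at the given conditions.

    The sodium correction is the standard logarithmic entropy term,
    0.368 cal/(mol*K) * ln[Na+] per stack (zero at the 1 M reference).
    """
    stacks, _ = _load_params()
    dh, ds = stacks[dinuc]
    ds = ds + 0.368 * math.log(cond.sodium)
    return dh - cond.kelvin * ds / 1000.0


def loop_dg(kind: str, size: int, cond: ThermoConditions) -> float:
    """Loop closure penalty, scaled from the tabulated 37 C value.

    Loop penalties are modelled as purely entropic, hence linear in absolute
    temperature; sizes beyond the table are extrapolated with the
    Jacobson-Stockmayer logarithmic term.
    """
    _, loops = _load_params()
    table = loops[kind]
    if size in table:
        g37 = table[size]
    else:
        top = max(table)
        g37 = table[top] + 1.75 * R_KCAL * T_REF * math.log(size / top)
    return g37 * cond.kelvin / T_REF


def pairs_wc(a: str, b: str) -> bool:
    return _WC.get(a) == b


# ---------------------------------------------------------------------------
# monomer (hairpin) minimum free energy
# ---------------------------------------------------------------------------


def hairpin_structure_energy(
    seq: str, pairs: Sequence[tuple[int, int]], cond: ThermoConditions | None = None
) -> float:
    """Free energy of an explicit single-hairpin structure.

    ``pairs`` is the helix from the outermost pair inward: strictly nested
    (i1 < i2 < ... < j2 < j1) Watson-Crick pairs closed by a terminal loop of
    at least ``MIN_HAIRPIN_LOOP`` bases.  Shared by the dynamic program's
    test oracle: the enumeration walks structures, this function prices them.
    """
    cond = cond or ThermoConditions()
    if not pairs:
        return 0.0
    for (i, j) in pairs:
        if not pairs_wc(seq[i], seq[j]):
            raise ValueError(f"positions {i},{j} are not a Watson-Crick pair")
    total = 0.0
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        g1, g2 = k - i - 1, j - l - 1
        if g1 < 0 or g2 < 0 or l <= k:
            raise ValueError("pairs must be strictly nested")
        if g1 == 0 and g2 == 0:
            total += stack_dg(seq[i] + seq[k], cond)
        elif g1 == 0 or g2 == 0:
            total += loop_dg("bulge_loop", g1 + g2, cond)
        else:
            total += loop_dg("internal_loop", g1 + g2, cond)
    i_last, j_last = pairs[-1]
    loop = j_last - i_last - 1
    if loop < MIN_HAIRPIN_LOOP:
        raise ValueError("terminal loop shorter than the minimum")
    total += loop_dg("hairpin_loop", loop, cond)
    return total


def monomer_mfe(seq: str, cond: ThermoConditions | None = None) -> float:
    """Minimum free energy over admissible hairpin structures, kcal/mol.

    Dynamic program over closed intervals: E(i,j) is the best energy of a
    structure whose outermost pair is (i,j); interior loops and bulges are
    capped at ``MAX_INTERIOR_LOOP`` unpaired bases.  Exterior unpaired bases
    are free.  Returns min(0, best), so an unstructured sequence scores 0.
    Deterministic; exact within its structure space.
    """
    cond = cond or ThermoConditions()
    _validate_seq(seq)
    n = len(seq)
    if n < MIN_HAIRPIN_LOOP + 2:
        return 0.0

    stacks, _ = _load_params()
    ds_salt = 0.368 * math.log(cond.sodium)
    tk = cond.kelvin
    sdg = {
        d: dh - tk * (ds + ds_salt) / 1000.0 for d, (dh, ds) in stacks.items()
    }
    hloop = [0.0] * n
    bloop = [0.0] * (MAX_INTERIOR_LOOP + 1)
    iloop = [0.0] * (MAX_INTERIOR_LOOP + 1)
    for size in range(MIN_HAIRPIN_LOOP, n):
        hloop[size] = loop_dg("hairpin_loop", size, cond)
    for size in range(1, MAX_INTERIOR_LOOP + 1):
        bloop[size] = loop_dg("bulge_loop", size, cond)
        if size >= 2:
            iloop[size] = loop_dg("internal_loop", size, cond)

    comp = [_WC[c] for c in seq]
    INF = math.inf
    E = [[INF] * n for _ in range(n)]
    best = 0.0
    max_gap = MAX_INTERIOR_LOOP
    for span in range(MIN_HAIRPIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            if comp[i] != seq[j]:
                continue
            e = hloop[j - i - 1]
            erow = E
            kmax = min(i + max_gap + 1, j - MIN_HAIRPIN_LOOP - 1)
            for k in range(i + 1, kmax + 1):
                g1 = k - i - 1
                rem = max_gap - g1
                row_k = erow[k]
                lmin = max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - rem)
                for l in range(j - 1, lmin - 1, -1):
                    inner = row_k[l]
                    if inner == INF:
                        continue
                    g2 = j - l - 1
                    if g1 == 0 and g2 == 0:
                        cand = inner + sdg[seq[i] + seq[k]]
                    elif g1 == 0 or g2 == 0:
                        cand = inner + bloop[g1 + g2]
                    else:
                        cand = inner + iloop[g1 + g2]
                    if cand < e:
                        e = cand
            E[i][j] = e
            if e < best:
                best = e
    return best


# ---------------------------------------------------------------------------
# heteroduplex
# ---------------------------------------------------------------------------


def duplex_dg(probe: str, target: str, cond: ThermoConditions | None = None) -> float:
    """Best ungapped probe/target heteroduplex free energy, kcal/mol.

    The target is a strand the probe may hybridize to (antiparallel).  For
    each alignment offset, consecutive complementary base pairs contribute
    nearest-neighbor stacks; a mismatch simply breaks the stacking run (no
    stabilizing term), so added mismatches can only raise the energy.
    Returns min over offsets, capped at 0 (no duplex).
    """
    cond = cond or ThermoConditions()
    _validate_seq(probe, what="probe")
    _validate_seq(target, what="target")
    stacks, _ = _load_params()
    ds_salt = 0.368 * math.log(cond.sodium)
    tk = cond.kelvin
    sdg = {d: dh - tk * (ds + ds_salt) / 1000.0 for d, (dh, ds) in stacks.items()}

    # orient the target 3'->5' against the probe's 5'->3' by reversing it;
    # then position k of the probe faces position k+off of the reversed target
    rt = target[::-1]
    np_, nt = len(probe), len(rt)
    best = 0.0
    for off in range(-(np_ - 2), nt - 1):
        lo = max(0, -off)
        hi = min(np_, nt - off)
        total = 0.0
        prev_paired = False
        for k in range(lo, hi):
            paired = pairs_wc(probe[k], rt[k + off])
            if paired and prev_paired:
                total += sdg[probe[k - 1] + probe[k]]
            prev_paired = paired
        if total < best:
            best = total
    return best


def delta_g_flag(monomer_dg: float, cutoff: float = MONOMER_DG_CUTOFF) -> bool:
    """True if the probe should be removed: folds *below* the cutoff.

    Strict inequality: a probe sitting exactly at the cutoff is kept.
    """
    return monomer_dg < cutoff
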