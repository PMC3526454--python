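"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration or per-offset
scoring, sharing no search logic with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np

from probelint.genome_map import revcomp
from probelint.thermo import (
    MAX_INTERIOR_LOOP,
    MIN_HAIRPIN_LOOP,
    ThermoConditions,
    hairpin_structure_energy,
    pairs_wc,
)

# ---------------------------------------------------------------------------
# exhaustive per-offset alignment scoring
# ---------------------------------------------------------------------------


def _max_run(query: str, window: str) -> int:
    best = run = 0
    for a, b in zip(query, window):
        run = run + 1 if a == b else 0
        best = max(best, run)
    return best


def oracle_scan(probe_seq: str, genome: dict[str, str], min_matches: int):
    """Score every offset on both strands; return qualifying placements as
    (chrom, start, strand, matches, max_run) tuples."""
    out = set()
    L = len(probe_seq)
    for chrom, seq in genome.items():
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(seq) < L:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, L)
        for strand, q in (("+", probe_seq), ("-", revcomp(probe_seq))):
            qc = np.frombuffer(q.encode(), dtype=np.uint8)
            matches = (win == qc).sum(axis=1)
            for off in np.nonzero(matches >= min_matches)[0]:
                off = int(off)
                out.add(
                    (
                        chrom,
                        off,
                        strand,
                        int(matches[off]),
                        _max_run(q, seq[off : off + L]),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# exhaustive hairpin-structure enumeration
# ---------------------------------------------------------------------------


def _chains(seq: str, i: int, j: int):
    """All nested pair chains starting with (i, j)."""
    if j - i - 1 >= MIN_HAIRPIN_LOOP:
        yield [(i, j)]
    for k in range(i + 1, j - MIN_HAIRPIN_LOOP):
        g1 = k - i - 1
        if g1 > MAX_INTERIOR_LOOP:
            break
        for l in range(j - 1, k + MIN_HAIRPIN_LOOP, -1):
            g2 = j - l - 1
            if g1 + g2 > MAX_INTERIOR_LOOP:
                break
            if not pairs_wc(seq[k], seq[l]):
                continue
            for chain in _chains(seq, k, l):
                yield [(i, j)] + chain


def oracle_hairpin_mfe(seq: str, cond: ThermoConditions | None = None) -> float:
    """Minimum energy over every legal single-hairpin structure, by complete
    enumeration (feasible for len(seq) <= 20)."""
    cond = cond or ThermoConditions()
    best = 0.0
    n = len(seq)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if not pairs_wc(seq[i], seq[j]):
                continue
            for chain in _chains(seq, i, j):
                e = hairpin_structure_energy(seq, chain, cond)
                best = min(best, e)
    return best


# ---------------------------------------------------------------------------
# rank-sum permutation enumeration
# ---------------------------------------------------------------------------


def oracle_ranksum_pvalue(a, b) -> float:
    """Two-sided rank-sum p by enumerating every label assignment (tie-free
    samples, n_a + n_b small)."""
    from scipy.stats import rankdata

    a, b = list(a), list(b)
    n_a, n = len(a), len(a) + len(b)
    ranks = rankdata(a + b)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    hits = total = 0
    for combo in itertools.combinations(range(1, n + 1), n_a):
        total += 1
        if abs(sum(combo) - mu) >= abs(w_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def oracle_substring_share(a: str, b: str, min_len: int) -> bool:
    """Do a and b (either strand of a) share an exact substring >= min_len?
    Checked over all offset pairs."""
    for s in (a, revcomp(a)):
        for i in range(len(s) - min_len + 1):
            if s[i : i + min_len] in b:
                return True
    return False
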