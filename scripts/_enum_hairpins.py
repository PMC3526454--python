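"""Standalone exhaustive hairpin-structure enumeration used by the
acceptance script as an independent check of the MFE dynamic program."""

from __future__ import annotations

from probelint.thermo import (
    MAX_INTERIOR_LOOP,
    MIN_HAIRPIN_LOOP,
    ThermoConditions,
    hairpin_structure_energy,
    pairs_wc,
)


def _chains(seq: str, i: int, j: int):
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
    cond = cond or ThermoConditions()
    best = 0.0
    n = len(seq)
    for i in range(n):
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n):
            if not pairs_wc(seq[i], seq[j]):
                continue
            for chain in _chains(seq, i, j):
                best = min(best, hairpin_structure_energy(seq, chain, cond))
    return best
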