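"""Independent brute-force oracles used across the test suite.

Everything here is deliberately written from first principles (explicit
codon-table strings, naive loops) and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np

_BASES = "TCAG"
# classic textbook codon-table strings, first/second/third base in TCAG order
_STANDARD = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_MITO = "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"


def oracle_translate(codon: str, table: str = "standard") -> str:
    s = _STANDARD if table == "standard" else _MITO
    i = _BASES.index(codon[0]) * 16 + _BASES.index(codon[1]) * 4 + _BASES.index(codon[2])
    return s[i]


def oracle_consequence(ref_codon: str, alt_codon: str, table: str = "standard") -> str:
    """Consequence by direct translation of both codons."""
    a, b = oracle_translate(ref_codon, table), oracle_translate(alt_codon, table)
    if a == b:
        return "synonymous"
    if b == "*":
        return "nonsense"
    if a == "*":
        return "other"
    return "missense"


def sense_codons(table: str = "standard") -> list[str]:
    return [
        x + y + z
        for x in "ACGT"
        for y in "ACGT"
        for z in "ACGT"
        if oracle_translate(x + y + z, table) != "*"
    ]


def oracle_count_occurrences(window: str, motif: str) -> int:
    """All-offsets occurrence count, overlapping matches included."""
    n = 0
    for i in range(len(window) - len(motif) + 1):
        if window[i : i + len(motif)] == motif:
            n += 1
    return n


def oracle_quantile(values, q: float) -> float:
    """Linear-interpolation empirical quantile from a sorted copy."""
    xs = sorted(values)
    if len(xs) == 1:
        return xs[0]
    h = q * (len(xs) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def oracle_spearman(a, b) -> float:
    """Rank both vectors (average ties), then Pearson."""

    def ranks(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x)
        r = np.empty(len(x))
        i = 0
        pos = 1.0
        sx = x[order]
        while i < len(x):
            j = i
            while j + 1 < len(x) and sx[j + 1] == sx[i]:
                j += 1
            avg = (pos + pos + (j - i)) / 2.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            pos += j - i + 1
            i = j + 1
        return r

    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra * rb).sum() / np.sqrt((ra**2).sum() * (rb**2).sum()))
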