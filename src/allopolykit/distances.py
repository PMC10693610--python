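"""Nucleotide-level distances (Jukes–Cantor) used for LTR ages and gene trees."""

from __future__ import annotations

import math

import numpy as np

#: p-distance at which the Jukes-Cantor correction diverges.
JC_SATURATION_P = 0.75

_VALID = frozenset("ACGT")


def jc_correct(p: float) -> float:
    """Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - 4p/3).

    Raises ValueError at or beyond the saturation point p >= 3/4, where the
    correction is undefined.
    """
    if p < 0:
        raise ValueError(f"proportion of differences must be >= 0, got {p}")
    if p >= JC_SATURATION_P:
        raise ValueError(f"saturated: p = {p} >= 3/4, JC distance undefined")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def p_distance(seq_a: str, seq_b: str) -> tuple[float, int]:
    """Proportion of differing sites and the number of comparable columns.

    Columns where either sequence has a character outside A/C/G/T (N, gap, ...)
    are excluded from both the numerator and denominator.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    valid_chars = np.array([c.encode() for c in "ACGT"])
    ok = np.isin(a, valid_chars) & np.isin(b, valid_chars)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no comparable (unambiguous) columns")
    diffs = int((a[ok] != b[ok]).sum())
    return diffs / n, n


def jc_distance(seq_a: str, seq_b: str) -> float:
    """JC-corrected nucleotide distance over unambiguous columns."""
    p, _ = p_distance(seq_a, seq_b)
    return jc_correct(p)
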