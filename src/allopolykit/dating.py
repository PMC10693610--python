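"""Divergence-to-time conversion (T = K / 2r) and LTR insertion-time dating.

A pair of sequences that stopped exchanging information T years ago and
accumulates substitutions at rate r per site per year per lineage is
separated by K = 2rT substitutions per site, so T = K / 2r. The same
identity dates whole-genome duplications from Ks peaks and LTR
retrotransposon insertions from the divergence of their (initially
identical) 5' and 3' long terminal repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

from .distances import JC_SATURATION_P, jc_correct, p_distance

YEARS_PER_MA = 1e6


@dataclass(frozen=True)
class RateCalibration:
    """A substitution rate r (per site per year) and where it came from."""

    r: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ValueError(f"rate must be positive, got {self.r}")


def divergence_time(k: float, cal: RateCalibration) -> float:
    """Time in Ma separating two sequences with divergence k: T = k / 2r."""
    if k < 0:
        raise ValueError(f"divergence must be >= 0, got {k}")
    return k / (2.0 * cal.r) / YEARS_PER_MA


def calibrate_rate(k_peak: float, known_time_ma: float, source: str = "calibrated") -> RateCalibration:
    """Rate implied by a divergence peak of known age: r = k / 2T.

    Inverse of :func:`divergence_time`; round-trips exactly.
    """
    if known_time_ma <= 0:
        raise ValueError(f"calibration time must be positive, got {known_time_ma}")
    r = k_peak / (2.0 * known_time_ma * YEARS_PER_MA)
    return RateCalibration(r=r, source=source)


def ltr_insertion_time(seq_5p: str, seq_3p: str, cal: RateCalibration) -> float | None:
    """Insertion age (Ma) of an LTR retrotransposon from its two LTRs.

    K is the JC-corrected distance between the aligned 5' and 3' LTRs over
    unambiguous columns; returns None when the pair is saturated
    (p >= 3/4), where the correction is undefined.
    """
    p, _ = p_distance(seq_5p, seq_3p)
    if p >= JC_SATURATION_P:
        return None
    return divergence_time(jc_correct(p), cal)
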