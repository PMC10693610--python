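"""Pairwise Ka/Ks by the Nei–Gojobori (1986) method and Ks-distribution peaks.

Ks — synonymous substitutions per synonymous site — acts as an approximate
molecular clock: syntenic gene pairs born by a whole-genome duplication (or
separated by speciation) at the same time share a common Ks peak, so the
peaks of a Ks distribution date the duplication/divergence events visible in
a genome. The engine computes per-pair Ka/Ks with NG86 fractional site
counting, pathway-averaged difference counting and Jukes–Cantor correction,
summarizes Ks per syntenic block, and fits Gaussian mixtures to Ks
distributions with BIC model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._codon import (
    AA,
    SYN_SITES,
    is_stop,
    is_valid_codon,
    pathway_differences,
)
from .distances import JC_SATURATION_P

#: Pairs with fewer comparable codons than this are flagged unusable.
MIN_USABLE_CODONS = 30

#: Blocks summarized from fewer usable pairs than this are flagged.
MIN_BLOCK_PAIRS = 5

#: Default cap on Ks values entering distribution/peak analysis.
DEFAULT_KS_CAP = 3.0

_ALLOWED = frozenset("ACGTN-")


def validate_codon_sequence(seq: str, name: str = "sequence") -> str:
    """Uppercase and validate a coding sequence (length % 3 == 0, ACGTN- only)."""
    s = seq.upper()
    if len(s) == 0 or len(s) % 3 != 0:
        raise ValueError(f"{name}: length {len(s)} is not a positive multiple of 3")
    bad = set(s) - _ALLOWED
    if bad:
        raise ValueError(f"{name}: illegal characters {sorted(bad)}")
    return s


@dataclass(frozen=True)
class KsResult:
    """NG86 counts and corrected distances for one aligned gene pair."""

    ka: float | None
    ks: float | None
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    saturated: bool
    usable_codons: int

    @property
    def usable(self) -> bool:
        return self.usable_codons >= MIN_USABLE_CODONS

    @property
    def omega(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks == 0:
            return None
        return self.ka / self.ks


def count_sites(seq: str) -> tuple[float, float]:
    """Total (nonsynonymous, synonymous) sites of an in-frame sequence.

    Each sense codon contributes 1/3 synonymous site per synonymous
    single-nucleotide neighbor; codons containing N or gaps and stop codons
    are skipped entirely.
    """
    s = validate_codon_sequence(seq)
    n_sites = 0.0
    s_sites = 0.0
    for i in range(0, len(s), 3):
        codon = s[i : i + 3]
        if not is_valid_codon(codon) or is_stop(codon):
            continue
        syn = SYN_SITES[codon]
        s_sites += syn
        n_sites += 3.0 - syn
    return n_sites, s_sites


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) differences of two codons."""
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if not is_valid_codon(c):
            raise ValueError(f"ambiguous or malformed codon {c!r}")
        if is_stop(c):
            raise ValueError(f"stop codon {c!r} cannot be compared")
    return pathway_differences(a, b)


def _comparable(codon_a: str, codon_b: str) -> bool:
    return (
        is_valid_codon(codon_a)
        and is_valid_codon(codon_b)
        and not is_stop(codon_a)
        and not is_stop(codon_b)
    )


def compute_ka_ks(seq_a: str, seq_b: str) -> KsResult:
    """NG86 Ka/Ks for a pair of in-frame aligned coding sequences.

    Site counts are averaged between the two sequences over the comparable
    codon columns (both codons unambiguous sense codons); pN and pS are
    Jukes–Cantor corrected. A proportion at or above 3/4 saturates the
    correction: the corresponding distance is None, and Ks saturation sets
    the ``saturated`` flag. Pairs with fewer than 30 comparable codons are
    returned flagged (``usable`` False) rather than raising.
    """
    a = validate_codon_sequence(seq_a, "seq_a")
    b = validate_codon_sequence(seq_b, "seq_b")
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")

    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    usable_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not _comparable(ca, cb):
            continue
        usable_codons += 1
        syn_a, syn_b = SYN_SITES[ca], SYN_SITES[cb]
        s_a += syn_a
        n_a += 3.0 - syn_a
        s_b += syn_b
        n_b += 3.0 - syn_b
        d_n, d_s = pathway_differences(ca, cb)
        nd += d_n
        sd += d_s

    n_sites = (n_a + n_b) / 2.0
    s_sites = (s_a + s_b) / 2.0

    if usable_codons < MIN_USABLE_CODONS:
        return KsResult(None, None, n_sites, s_sites, nd, sd, False, usable_codons)

    def _correct(p: float) -> float | None:
        if p >= JC_SATURATION_P:
            return None
        return -0.75 * math.log1p(-4.0 * p / 3.0)

    p_n = nd / n_sites if n_sites > 0 else 0.0
    p_s = sd / s_sites if s_sites > 0 else 0.0
    ka = _correct(p_n)
    ks = _correct(p_s)
    return KsResult(ka, ks, n_sites, s_sites, nd, sd, ks is None, usable_codons)


def block_summary(
    anchors: pd.DataFrame,
    results: dict[tuple[str, str], KsResult],
    stat: str = "mean",
) -> pd.DataFrame:
    """Per-syntenic-block Ks summaries from per-pair results.

    Saturated and unusable pairs are excluded; blocks with fewer than
    MIN_BLOCK_PAIRS usable pairs carry ``flagged`` True and a NaN summary.
    ``stat`` is "mean" (the conventional block average) or "median".
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    required = {"gene_a", "gene_b", "block_id"}
    if not required.issubset(anchors.columns):
        raise ValueError(f"anchor table must have columns {sorted(required)}")

    rows = []
    for block_id, grp in anchors.groupby("block_id", sort=True):
        ks_vals = []
        n_pairs = 0
        for ga, gb in zip(grp["gene_a"], grp["gene_b"]):
            if pd.isna(ga) or pd.isna(gb):
                continue
            key = (ga, gb)
            if key not in results:
                raise KeyError(f"no Ks result for anchor pair {key} in block {block_id}")
            n_pairs += 1
            res = results[key]
            if res.usable and not res.saturated and res.ks is not None:
                ks_vals.append(res.ks)
        n_usable = len(ks_vals)
        if n_usable >= MIN_BLOCK_PAIRS:
            summary = float(np.mean(ks_vals) if stat == "mean" else np.median(ks_vals))
            flagged = False
        else:
            summary = float(np.mean(ks_vals) if stat == "mean" else np.median(ks_vals)) if ks_vals else float("nan")
            flagged = True
        rows.append(
            {
                "block_id": block_id,
                "n_pairs": n_pairs,
                "n_usable": n_usable,
                "ks": summary,
                "flagged": flagged,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PeakModel:
    """Gaussian-mixture model of a Ks distribution, components sorted by mean."""

    k: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    bic: dict[int, float] = field(default_factory=dict)


def fit_ks_peaks(
    values,
    k_max: int = 4,
    seed: int = 0,
    ks_cap: float = DEFAULT_KS_CAP,
    min_values: int = 50,
) -> PeakModel:
    """Fit 1..k_max Gaussian mixtures to a Ks sample and select k by BIC.

    Values outside (0, ks_cap] are dropped first (the saturation regime is
    uninformative for peak dating). EM runs from 10 seeded k-means
    initializations per k; ties in BIC resolve toward the smaller k.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    x = x[(x > 0) & (x <= ks_cap)]
    if x.size < min_values:
        raise ValueError(f"need at least {min_values} usable Ks values, got {x.size}")
    if np.std(x) < 1e-12:
        raise ValueError("degenerate input: all Ks values identical")
    X = x.reshape(-1, 1)

    bics: dict[int, float] = {}
    fits: dict[int, GaussianMixture] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=10,
            init_params="kmeans",
            random_state=seed,
            reg_covar=1e-8,
        )
        gm.fit(X)
        bics[k] = float(gm.bic(X))
        fits[k] = gm

    best_k = min(sorted(bics), key=lambda k: bics[k])
    gm = fits[best_k]
    order = np.argsort(gm.means_.ravel())
    means = tuple(float(m) for m in gm.means_.ravel()[order])
    sds = tuple(float(np.sqrt(gm.covariances_[i].ravel()[0])) for i in order)
    weights = tuple(float(w) for w in gm.weights_[order])
    return PeakModel(best_k, means, sds, weights, bics)
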