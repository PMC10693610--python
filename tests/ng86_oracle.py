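"""Brute-force Nei–Gojobori oracle, independent of the package implementation.

Every quantity is derived directly from Biopython's translation of single
codons: fractional sites by enumerating the nine mutational neighbors,
differences by enumerating all minimal pathways, distances by applying the
Jukes–Cantor formula verbatim. Deliberately slow and literal.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations

from Bio.Seq import Seq

NUC = "ACGT"


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(codon: str) -> float:
    syn = 0
    for pos in range(3):
        for nt in NUC:
            if nt == codon[pos]:
                continue
            nb = codon[:pos] + nt + codon[pos + 1 :]
            if _aa(nb) != "*" and _aa(nb) == _aa(codon):
                syn += 1
    return syn / 3.0


def oracle_count_sites(seq: str) -> tuple[float, float]:
    n = s = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if set(codon) - set(NUC) or _aa(codon) == "*":
            continue
        sc = oracle_syn_sites(codon)
        s += sc
        n += 3.0 - sc
    return n, s


def oracle_count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in permutations(diff):
        cur = codon_a
        nd = sd = 0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*":
                hits_stop = True
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if hits_stop else clean).append((nd, sd))
    use = clean if clean else dirty
    return (
        sum(x[0] for x in use) / len(use),
        sum(x[1] for x in use) / len(use),
    )


def oracle_ka_ks(seq_a: str, seq_b: str) -> dict:
    """Full NG86 Ka/Ks computed codon by codon, the slow way."""
    n_a = s_a = n_b = s_b = nd = sd = 0.0
    usable = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        skip = (
            set(ca) - set(NUC)
            or set(cb) - set(NUC)
            or _aa(ca) == "*"
            or _aa(cb) == "*"
        )
        if skip:
            continue
        usable += 1
        sa, sb = oracle_syn_sites(ca), oracle_syn_sites(cb)
        s_a += sa
        n_a += 3 - sa
        s_b += sb
        n_b += 3 - sb
        d_n, d_s = oracle_count_differences(ca, cb)
        nd += d_n
        sd += d_s
    n_sites = (n_a + n_b) / 2
    s_sites = (s_a + s_b) / 2

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1 - 4 * p / 3)

    p_n = nd / n_sites if n_sites else 0.0
    p_s = sd / s_sites if s_sites else 0.0
    return {
        "n_sites": n_sites,
        "s_sites": s_sites,
        "nd": nd,
        "sd": sd,
        "usable_codons": usable,
        "ka": jc(p_n),
        "ks": jc(p_s),
    }


def random_codon_pair_set(rng, n_pairs: int, n_codons: int, mut_p: float = 0.15):
    """Random sense-codon sequences with point mutations for oracle checks."""
    sense = [
        a + b + c
        for a in NUC
        for b in NUC
        for c in NUC
        if _aa(a + b + c) != "*"
    ]
    pairs = []
    for _ in range(n_pairs):
        codons = [sense[rng.integers(len(sense))] for _ in range(n_codons)]
        seq_a = "".join(codons)
        chars = list(seq_a)
        for j in range(len(chars)):
            if rng.random() < mut_p:
                chars[j] = NUC[rng.integers(4)]
        pairs.append((seq_a, "".join(chars)))
    return pairs
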