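"""Genetic-code tables shared by the Ka/Ks engine and the sequence simulator.

Everything here is derived once, at import time, from Biopython's standard
nuclear codon table, so the counting code and the simulator can never drift
apart on what "synonymous" means.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"

#: All 64 codons in lexicographic order; index = 16*i1 + 4*i2 + i3.
CODONS: tuple[str, ...] = tuple("".join(c) for c in product(NUCLEOTIDES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]

#: Amino acid per codon, with '*' for the three stop codons.
AA: dict[str, str] = dict(_table.forward_table)
for _stop in _table.stop_codons:
    AA[_stop] = "*"

STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_valid_codon(codon: str) -> bool:
    """True for an unambiguous, fully resolved codon (no N or gap)."""
    return codon in CODON_INDEX


def neighbors(codon: str) -> list[str]:
    """The 9 single-nucleotide mutational neighbors of a codon."""
    out = []
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt != codon[pos]:
                out.append(codon[:pos] + nt + codon[pos + 1 :])
    return out


# Fractional synonymous site count per sense codon: each of the 9 neighbors
# contributes 1/3 site, synonymous if it encodes the same amino acid.
# Mutations to stop codons count as nonsynonymous, which keeps the identity
# n_sites + s_sites = 3 per codon exact.
SYN_SITES: dict[str, float] = {}
for _c in SENSE_CODONS:
    _syn = sum(1 for nb in neighbors(_c) if not is_stop(nb) and AA[nb] == AA[_c])
    SYN_SITES[_c] = _syn / 3.0


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Nei–Gojobori pathway-averaged (nonsyn, syn) difference counts.

    All minimal mutational pathways between the two codons are enumerated;
    pathways passing through a stop codon are discarded (unless every
    pathway does, in which case all are used); each step is scored
    synonymous or nonsynonymous and counts are averaged over pathways.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return (0.0, 0.0)
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        nd = sd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if is_stop(nxt) and nxt != codon_b:
                through_stop = True
            if AA[cur] == AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((nd, sd))
    paths = valid if valid else blocked
    nd_mean = sum(p[0] for p in paths) / len(paths)
    sd_mean = sum(p[1] for p in paths) / len(paths)
    return (nd_mean, sd_mean)
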