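"""Allo- vs auto-tetraploid and shared vs independent WGD tests.

Two lines of evidence distinguish polyploid origins:

* **Quartet topology.** For two tetraploid species A and B, each collinear
  gene has copies A1, A2 (species A) and B1, B2 (species B). If the
  duplication predates the species split (a shared allotetraploidy), each A
  copy is sister to a B copy — the unrooted in-group quartet is
  A1B1|A2B2 (or A1B2|A2B1; copy numbering carries no intrinsic pairing).
  If each species duplicated independently, the copies sister within
  species: A1A2|B1B2. Counting gene trees in each class tests which
  history the genome supports.

* **Ks asymmetry.** In an autotetraploid, both duplicated chromosomes are
  equidistant from any reference chromosome, so their Ks distributions
  against it coincide; in an allotetraploid the two subgenomes diverged
  from the reference at different times, so the distributions differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import dendropy
import numpy as np
from scipy import stats

from .distances import JC_SATURATION_P, jc_correct, p_distance

INGROUP_LABELS = frozenset({"A1", "A2", "B1", "B2"})
QUARTET_LABELS = frozenset({"A1", "A2", "B1", "B2", "OUT"})


class Topology(str, Enum):
    SHARED = "SHARED"
    INDEPENDENT = "INDEPENDENT"
    OTHER = "OTHER"


class AsymmetryVerdict(str, Enum):
    ALLO_CONSISTENT = "ALLO_CONSISTENT"
    AUTO_CONSISTENT = "AUTO_CONSISTENT"
    INCONCLUSIVE = "INCONCLUSIVE"


@dataclass(frozen=True)
class TopologyCall:
    gene_id: str
    call: Topology


def jc_distance_matrix(
    sequences: dict[str, str], gene_id: str = ""
) -> tuple[list[str], np.ndarray]:
    """Symmetric JC-corrected distance matrix over a labeled sequence set."""
    labels = list(sequences)
    n = len(labels)
    mat = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        p, _ = p_distance(sequences[labels[i]], sequences[labels[j]])
        if p >= JC_SATURATION_P:
            raise ValueError(
                f"saturated pair ({labels[i]}, {labels[j]})"
                + (f" in gene {gene_id}" if gene_id else "")
            )
        mat[i, j] = mat[j, i] = jc_correct(p)
    return labels, mat


def nj_tree(labels: list[str], distances: np.ndarray) -> str:
    """Neighbor-joining tree (Newick, unrooted trifurcation at the base).

    Deterministic: ties in the Q criterion are broken by the smallest
    (i, j) taxon-index pair in the original input order.
    """
    d = np.asarray(distances, dtype=float)
    n = len(labels)
    if n < 4:
        raise ValueError("neighbor joining needs at least 4 taxa")
    if d.shape != (n, n) or not np.all(np.isfinite(d)):
        raise ValueError("distance matrix must be square and finite")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    nodes = [f"{lab}" for lab in labels]
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}
    next_id = n
    node_newick = {i: nodes[i] for i in range(n)}

    def _d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(_d(i, k) for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * _d(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        dij = _d(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        node_newick[next_id] = f"({node_newick[i]}:{li:.10g},{node_newick[j]}:{lj:.10g})"
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_id), max(k, next_id))] = 0.5 * (_d(i, k) + _d(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    la = 0.5 * (_d(a, b) + _d(a, c) - _d(b, c))
    lb = 0.5 * (_d(a, b) + _d(b, c) - _d(a, c))
    lc = 0.5 * (_d(a, c) + _d(b, c) - _d(a, b))
    parts = ",".join(
        f"{node_newick[x]}:{max(l, 0.0):.10g}" for x, l in ((a, la), (b, lb), (c, lc))
    )
    return f"({parts});"


def _as_tree(tree: str | dendropy.Tree) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(data=tree, schema="newick")


def classify_quartet(tree: str | dendropy.Tree, gene_id: str = "") -> TopologyCall:
    """Classify a 5-leaf gene tree as SHARED / INDEPENDENT / OTHER.

    Rooted at OUT, a supporting tree consists of two in-group cherries
    with the outgroup on the central edge. Both cherries {Ai,Bj} and
    {Ak,Bl} present is SHARED (each A copy sisters a B copy; the copy
    indexing carries no intrinsic pairing, so both pairings count);
    cherries {A1,A2} and {B1,B2} is INDEPENDENT. Anything else —
    multifurcations, or the outgroup nesting inside the in-group — is
    OTHER.
    """
    t = _as_tree(tree)
    leaves = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    if leaves != set(QUARTET_LABELS):
        raise ValueError(f"expected leaf labels {sorted(QUARTET_LABELS)}, got {sorted(leaves)}")

    # nontrivial splits, normalized to the side not containing OUT
    splits: set[frozenset[str]] = set()
    for node in t.preorder_internal_node_iter():
        below = {leaf.taxon.label for leaf in node.leaf_iter()}
        if below == leaves:
            continue
        side = frozenset(below) if "OUT" not in below else frozenset(leaves - below)
        if 2 <= len(side) <= 3:
            splits.add(side)

    cherries = {s for s in splits if len(s) == 2 and frozenset(INGROUP_LABELS - s) in splits}
    if not cherries:
        return TopologyCall(gene_id, Topology.OTHER)
    if frozenset({"A1", "A2"}) in cherries:
        return TopologyCall(gene_id, Topology.INDEPENDENT)
    return TopologyCall(gene_id, Topology.SHARED)


def shared_wgd_support(calls: list[TopologyCall]) -> dict:
    """Counts and fractions of gene trees per topology class."""
    if not calls:
        raise ValueError("no topology calls to summarize")
    counts = {t.value: 0 for t in Topology}
    for c in calls:
        counts[Topology(c.call).value] += 1
    total = len(calls)
    fractions = {k: v / total for k, v in counts.items()}
    return {
        "n_trees": total,
        "counts": counts,
        "fractions": fractions,
        "fraction_shared": fractions[Topology.SHARED.value],
        "percent_shared": round(100.0 * fractions[Topology.SHARED.value], 1),
    }


@dataclass(frozen=True)
class AsymmetryResult:
    """Outcome of the allo- vs auto-tetraploid Ks-asymmetry test."""

    n1: int
    n2: int
    statistic: float
    p_value: float
    mode1: float
    mode2: float
    delta_mode: float
    verdict: AsymmetryVerdict


def _kde_mode(values: np.ndarray) -> float:
    """Mode of a sample via a Gaussian KDE on a fine grid."""
    v = np.asarray(values, dtype=float)
    if v.size < 3 or np.std(v) < 1e-12:
        return float(np.median(v))
    kde = stats.gaussian_kde(v)
    lo, hi = v.min(), v.max()
    pad = 0.05 * (hi - lo)
    grid = np.linspace(lo - pad, hi + pad, 512)
    return float(grid[np.argmax(kde(grid))])


def allo_auto_test(
    ks_ref_vs_dup1,
    ks_ref_vs_dup2,
    alpha: float = 0.05,
    min_effect: float = 0.05,
    min_n: int = 20,
) -> AsymmetryResult:
    """Compare the Ks distributions of two duplicate chromosomes vs a reference.

    Mann–Whitney rank test plus a difference-of-modes effect size.
    ALLO_CONSISTENT requires both significance (p < alpha) and a material
    mode shift (|Δmode| >= min_effect, in Ks units); AUTO_CONSISTENT
    requires neither; disagreement or thin data is INCONCLUSIVE.
    """
    x1 = np.asarray([v for v in ks_ref_vs_dup1 if v is not None and np.isfinite(v)])
    x2 = np.asarray([v for v in ks_ref_vs_dup2 if v is not None and np.isfinite(v)])
    if len(x1) < min_n or len(x2) < min_n:
        m1 = _kde_mode(x1) if len(x1) else float("nan")
        m2 = _kde_mode(x2) if len(x2) else float("nan")
        return AsymmetryResult(
            len(x1), len(x2), float("nan"), float("nan"), m1, m2,
            float(abs(m1 - m2)), AsymmetryVerdict.INCONCLUSIVE,
        )
    stat, p = stats.mannwhitneyu(x1, x2, alternative="two-sided")
    m1, m2 = _kde_mode(x1), _kde_mode(x2)
    delta = abs(m1 - m2)
    if p < alpha and delta >= min_effect:
        verdict = AsymmetryVerdict.ALLO_CONSISTENT
    elif p >= alpha and delta < min_effect:
        verdict = AsymmetryVerdict.AUTO_CONSISTENT
    else:
        verdict = AsymmetryVerdict.INCONCLUSIVE
    return AsymmetryResult(len(x1), len(x2), float(stat), float(p), m1, m2, float(delta), verdict)


def quartet_topology(sequences: dict[str, str], gene_id: str = "") -> TopologyCall:
    """Convenience: JC distances -> NJ tree -> topology call for one quartet."""
    labels, mat = jc_distance_matrix(sequences, gene_id=gene_id)
    return classify_quartet(nj_tree(labels, mat), gene_id=gene_id)
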