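"""Subgenome fractionation, homoeolog expression bias (HEB), differential
expression, orthologous-DEG concordance, and tandem-duplicate DE summaries.

After an allopolyploidy event the two subgenomes may fractionate (lose
duplicated copies) at different rates and may express homoeologs unequally.
This module quantifies both, plus cross-species conservation of stress
responses: orthologs that are differentially expressed in both species are
scored as functionally conserved when they respond in the same tissue(s)
in the same direction under the same treatment.

The DE engine is a Welch t-test on log2(TPM + 1) with Benjamini–Hochberg
correction; a gene is differentially expressed at |log2 fold change| >= 1
(twofold) and adjusted p below the FDR threshold. Externally produced DE
tables (e.g. from a negative-binomial model) can be supplied to the
concordance and tandem summaries in place of this engine's output.
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FC = 2.0
DEFAULT_FDR = 0.05
#: Homoeolog pair testable in a condition if either copy reaches this TPM.
MIN_TPM = 1.0
PSEUDOCOUNT = 1.0


class HebCall(str, Enum):
    A_BIASED = "A_BIASED"
    B_BIASED = "B_BIASED"
    UNBIASED = "UNBIASED"
    UNTESTABLE = "UNTESTABLE"


# ---------------------------------------------------------------------------
# fractionation

def retention_profile(anchors: pd.DataFrame) -> pd.DataFrame:
    """Per-reference-chromosome counts of retained and lost A/B copies.

    Expects an anchor table with ``gene_a``/``gene_b`` (NaN/None = copy
    lost) and ``chr_ref``. A row lacking both copies is invalid.
    """
    if len(anchors) == 0:
        raise ValueError("empty anchor table")
    has_a = anchors["gene_a"].notna()
    has_b = anchors["gene_b"].notna()
    if ((~has_a) & (~has_b)).any():
        raise ValueError("anchor rows must retain at least one subgenome copy")
    df = pd.DataFrame(
        {
            "chr_ref": anchors["chr_ref"],
            "retained_a": has_a.astype(int),
            "retained_b": has_b.astype(int),
            "lost_a": (~has_a).astype(int),
            "lost_b": (~has_b).astype(int),
        }
    )
    prof = df.groupby("chr_ref", sort=True).sum()
    prof.insert(0, "n_anchors", anchors.groupby("chr_ref", sort=True).size())
    return prof


def fractionation_bias_test(profile: pd.DataFrame) -> dict:
    """Exact binomial test of A-loss vs B-loss among singletons (null 0.5).

    Tests each chromosome and the pooled genome; per-chromosome p-values
    are BH-adjusted. Chromosomes without singletons are flagged
    (test undefined); singleton totals below 10 are flagged low-power.
    """
    rows = []
    for chrom, row in profile.iterrows():
        la, lb = int(row["lost_a"]), int(row["lost_b"])
        n = la + lb
        if n == 0:
            p = float("nan")
            flag = "no_singletons"
        else:
            p = float(stats.binomtest(la, n, 0.5).pvalue)
            flag = "low_power" if n < 10 else ""
        rows.append({"chr_ref": chrom, "lost_a": la, "lost_b": lb, "p": p, "flag": flag})
    per_chr = pd.DataFrame(rows).set_index("chr_ref")
    defined = per_chr["p"].notna()
    per_chr["p_adj"] = np.nan
    if defined.any():
        per_chr.loc[defined, "p_adj"] = multipletests(per_chr.loc[defined, "p"], method="fdr_bh")[1]

    la, lb = int(profile["lost_a"].sum()), int(profile["lost_b"].sum())
    n = la + lb
    global_p = float(stats.binomtest(la, n, 0.5).pvalue) if n > 0 else float("nan")
    return {
        "per_chromosome": per_chr,
        "global_lost_a": la,
        "global_lost_b": lb,
        "global_p": global_p,
        "global_flag": "no_singletons" if n == 0 else ("low_power" if n < 10 else ""),
    }


# ---------------------------------------------------------------------------
# differential expression

def sample_conditions(columns) -> pd.Series:
    """Map ``condition_replicate`` column names to their condition."""
    return pd.Series({c: c.rsplit("_", 1)[0] for c in columns})


def _welch_log2(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test on log2(TPM+1); rows are genes.

    Returns (log2 fold change b-over-a, p-values); rows with no variance
    in both groups get p = 1 when means are equal, else p = 0.
    """
    la = np.log2(a + PSEUDOCOUNT)
    lb = np.log2(b + PSEUDOCOUNT)
    lfc = lb.mean(axis=1) - la.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # constant rows are expected (e.g. untestable pairs); handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    p[degenerate & (np.abs(lfc) < 1e-12)] = 1.0
    p[degenerate & (np.abs(lfc) >= 1e-12)] = 0.0
    return lfc, p


def call_de(
    expr: pd.DataFrame,
    condition_control: str,
    condition_treatment: str,
    fc_threshold: float = DEFAULT_FC,
    fdr: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Per-gene DE calls for treatment vs control.

    ``expr`` is genes x samples TPM with ``condition_replicate`` column
    names. DE requires |log2FC| >= log2(fc_threshold) and BH-adjusted
    p < fdr; ``direction`` is 'up'/'down' for DE genes, 'ns' otherwise.
    """
    cond = sample_conditions(expr.columns)
    ctrl_cols = cond.index[cond == condition_control]
    trt_cols = cond.index[cond == condition_treatment]
    for name, cols in ((condition_control, ctrl_cols), (condition_treatment, trt_cols)):
        if len(cols) < 2:
            raise ValueError(f"condition {name!r} needs >= 2 replicates, found {len(cols)}")
    lfc, p = _welch_log2(expr[ctrl_cols].to_numpy(float), expr[trt_cols].to_numpy(float))
    padj = multipletests(p, method="fdr_bh")[1]
    de = (np.abs(lfc) >= np.log2(fc_threshold)) & (padj < fdr)
    direction = np.where(de, np.where(lfc > 0, "up", "down"), "ns")
    return pd.DataFrame(
        {"log2fc": lfc, "p": p, "padj": padj, "de": de, "direction": direction},
        index=expr.index,
    )


# ---------------------------------------------------------------------------
# homoeolog expression bias

def heb_classify(
    expr: pd.DataFrame,
    pairs: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC,
    fdr: float = DEFAULT_FDR,
    min_tpm: float = MIN_TPM,
) -> pd.DataFrame:
    """Per-pair, per-condition homoeolog expression bias calls.

    ``pairs`` needs columns pair_id, gene_a, gene_b mapping into
    ``expr``'s index. Within each condition the A and B copies are
    compared across replicates with the DE engine's test; a pair whose two
    copies both stay below ``min_tpm`` in a condition is UNTESTABLE there.
    B_BIASED means the B copy is significantly higher (log2 B/A >= 1 at
    the FDR), mirrored for A_BIASED. BH correction runs within condition
    across the testable pairs.
    """
    missing = [
        g
        for col in ("gene_a", "gene_b")
        for g in pairs[col]
        if g not in expr.index
    ]
    if missing:
        raise KeyError(f"homoeolog genes absent from expression table: {missing[:5]}...")
    cond = sample_conditions(expr.columns)
    a_mat = expr.loc[pairs["gene_a"]].to_numpy(float)
    b_mat = expr.loc[pairs["gene_b"]].to_numpy(float)
    lfc_gate = np.log2(fc_threshold)

    out = []
    for condition in cond.unique():
        cols = np.flatnonzero((cond == condition).to_numpy())
        a = a_mat[:, cols]
        b = b_mat[:, cols]
        testable = (a.max(axis=1) >= min_tpm) | (b.max(axis=1) >= min_tpm)
        lfc, p = _welch_log2(a, b)
        padj = np.full(len(pairs), np.nan)
        if testable.any():
            padj[testable] = multipletests(p[testable], method="fdr_bh")[1]
        call = np.full(len(pairs), HebCall.UNBIASED.value, dtype=object)
        sig = testable & (padj < fdr)
        call[sig & (lfc >= lfc_gate)] = HebCall.B_BIASED.value
        call[sig & (lfc <= -lfc_gate)] = HebCall.A_BIASED.value
        call[~testable] = HebCall.UNTESTABLE.value
        out.append(
            pd.DataFrame(
                {
                    "pair_id": pairs["pair_id"].to_numpy(),
                    "condition": condition,
                    "call": call,
                    "log2_ratio": lfc,
                    "padj": padj,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def heb_summary(calls: pd.DataFrame) -> dict:
    """Aggregate HEB calls across conditions.

    Reports pairs biased in >= 1 condition, pairs biased in every
    condition with a consistent direction, the fraction of pair x
    condition comparisons biased toward each subgenome, and the B-share
    among biased comparisons per condition. Percentages are rounded to one
    decimal.
    """
    if len(calls) == 0:
        raise ValueError("no HEB calls to summarize")
    conditions = calls["condition"].unique()
    n_conditions = len(conditions)
    biased = calls["call"].isin([HebCall.A_BIASED.value, HebCall.B_BIASED.value])
    per_pair = calls.assign(biased=biased).groupby("pair_id")
    n_pairs = per_pair.ngroups

    biased_any = int((per_pair["biased"].sum() >= 1).sum())

    def _all_same_direction(grp: pd.DataFrame) -> bool:
        return (
            len(grp) == n_conditions
            and (grp["call"] == HebCall.A_BIASED.value).all()
            or len(grp) == n_conditions
            and (grp["call"] == HebCall.B_BIASED.value).all()
        )

    biased_all = int(
        calls.groupby("pair_id", sort=False)[["call"]]
        .apply(_all_same_direction)
        .sum()
    )

    n_comparisons = len(calls)
    n_b = int((calls["call"] == HebCall.B_BIASED.value).sum())
    n_a = int((calls["call"] == HebCall.A_BIASED.value).sum())

    per_condition = {}
    for condition in conditions:
        sub = calls[calls["condition"] == condition]
        nb = int((sub["call"] == HebCall.B_BIASED.value).sum())
        na = int((sub["call"] == HebCall.A_BIASED.value).sum())
        per_condition[condition] = {
            "n_biased": nb + na,
            "b_share_pct": round(100.0 * nb / (nb + na), 1) if nb + na else 0.0,
        }

    return {
        "n_pairs": n_pairs,
        "n_conditions": n_conditions,
        "n_comparisons": n_comparisons,
        "biased_in_any": biased_any,
        "biased_in_all": biased_all,
        "b_biased_comparisons": n_b,
        "a_biased_comparisons": n_a,
        "b_biased_pct": round(100.0 * n_b / n_comparisons, 1),
        "a_biased_pct": round(100.0 * n_a / n_comparisons, 1),
        "per_condition": per_condition,
    }


# ---------------------------------------------------------------------------
# cross-species orthologous-DEG concordance

TISSUES = ("shoot", "root")


def _patterns(deg: pd.DataFrame, treatment: str) -> pd.DataFrame:
    """Per-gene (shoot, root) direction pattern for one treatment."""
    sub = deg[deg["treatment"] == treatment]
    wide = sub.pivot_table(
        index="gene", columns="tissue", values="direction", aggfunc="first"
    )
    for t in TISSUES:
        if t not in wide.columns:
            wide[t] = "ns"
    return wide[list(TISSUES)].fillna("ns")


def ortholog_deg_concordance(
    deg_s1: pd.DataFrame,
    deg_s2: pd.DataFrame,
    orthologs: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conservation of expression responses between orthologs of two species.

    ``deg_s1``/``deg_s2`` are long tables with columns gene, treatment,
    tissue ('shoot'/'root'), direction ('up'/'down'/'ns'); ``orthologs``
    maps gene_s1 to gene_s2 one-to-one. For each treatment, only ortholog
    pairs DE in both species (any tissue) are scored; CONSERVED means an
    identical (shoot, root) direction pattern, including shared
    non-significance per tissue. Returns (per-pair calls, per-treatment
    summary with integer-rounded conserved percentages).
    """
    if orthologs["gene_s1"].duplicated().any() or orthologs["gene_s2"].duplicated().any():
        raise ValueError("ortholog map has colliding (duplicated) gene entries")
    treatments = sorted(set(deg_s1["treatment"]) | set(deg_s2["treatment"]))
    calls = []
    for treatment in treatments:
        p1 = _patterns(deg_s1, treatment)
        p2 = _patterns(deg_s2, treatment)
        for g1, g2 in zip(orthologs["gene_s1"], orthologs["gene_s2"]):
            pat1 = tuple(p1.loc[g1]) if g1 in p1.index else ("ns", "ns")
            pat2 = tuple(p2.loc[g2]) if g2 in p2.index else ("ns", "ns")
            de1 = any(d != "ns" for d in pat1)
            de2 = any(d != "ns" for d in pat2)
            if not (de1 and de2):
                continue
            calls.append(
                {
                    "gene_s1": g1,
                    "gene_s2": g2,
                    "treatment": treatment,
                    "pattern_s1": "/".join(pat1),
                    "pattern_s2": "/".join(pat2),
                    "verdict": "CONSERVED" if pat1 == pat2 else "DIVERGENT",
                }
            )
    calls_df = pd.DataFrame(
        calls, columns=["gene_s1", "gene_s2", "treatment", "pattern_s1", "pattern_s2", "verdict"]
    )
    summary_rows = []
    for treatment in treatments:
        sub = calls_df[calls_df["treatment"] == treatment]
        n = len(sub)
        n_cons = int((sub["verdict"] == "CONSERVED").sum())
        summary_rows.append(
            {
                "treatment": treatment,
                "n_pairs": n,
                "n_conserved": n_cons,
                "conserved_pct": int(round(100.0 * n_cons / n)) if n else 0,
            }
        )
    return calls_df, pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# tandem duplicates

def tandem_deg_summary(clusters: pd.DataFrame, de_genes: set[str]) -> dict:
    """DE burden among tandemly duplicated genes.

    ``clusters`` has columns gene, cluster_id partitioning the tandem gene
    set; ``de_genes`` is the set of genes DE in >= 1 tissue/treatment.
    Reports (i) tandem genes DE at least once and (ii) clusters with >= 2
    DE copies; percentages to one decimal.
    """
    if clusters["gene"].duplicated().any():
        dup = clusters.loc[clusters["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"gene {dup!r} assigned to more than one tandem cluster")
    n_genes = len(clusters)
    if n_genes == 0:
        raise ValueError("empty tandem cluster table")
    is_de = clusters["gene"].isin(de_genes)
    n_de = int(is_de.sum())
    per_cluster = clusters.assign(de=is_de).groupby("cluster_id")["de"].sum()
    n_clusters = len(per_cluster)
    n_multi = int((per_cluster >= 2).sum())
    return {
        "n_tandem_genes": n_genes,
        "n_de_genes": n_de,
        "de_gene_pct": round(100.0 * n_de / n_genes, 1),
        "n_clusters": n_clusters,
        "n_clusters_multi_de": n_multi,
        "clusters_multi_de_pct": round(100.0 * n_multi / n_clusters, 1),
    }
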