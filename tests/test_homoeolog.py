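"""Fractionation, DE, HEB, concordance and tandem-duplicate statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from allopolykit.homoeolog import (
    call_de,
    fractionation_bias_test,
    heb_classify,
    heb_summary,
    ortholog_deg_concordance,
    retention_profile,
    tandem_deg_summary,
)
from allopolykit.simulate import BiasSpec, simulate_expression


def _anchor_rows(chrom, n_pairs, n_a_only, n_b_only):
    rows = []
    for i in range(n_pairs):
        rows.append({"gene_a": f"{chrom}a{i}", "gene_b": f"{chrom}b{i}", "chr_ref": chrom})
    for i in range(n_a_only):
        rows.append({"gene_a": f"{chrom}sa{i}", "gene_b": None, "chr_ref": chrom})
    for i in range(n_b_only):
        rows.append({"gene_a": None, "gene_b": f"{chrom}sb{i}", "chr_ref": chrom})
    return rows


class TestRetentionProfile:
    def test_toy_counting(self):
        anchors = pd.DataFrame(_anchor_rows("chr01", 10, 3, 2))
        prof = retention_profile(anchors)
        assert prof.loc["chr01", "retained_a"] == 13
        assert prof.loc["chr01", "retained_b"] == 12
        assert prof.loc["chr01", "lost_a"] == 2
        assert prof.loc["chr01", "lost_b"] == 3

    def test_all_pairs_equal_counts(self):
        anchors = pd.DataFrame(_anchor_rows("chr01", 20, 0, 0))
        prof = retention_profile(anchors)
        assert prof.loc["chr01", "retained_a"] == prof.loc["chr01", "retained_b"] == 20

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            retention_profile(pd.DataFrame(columns=["gene_a", "gene_b", "chr_ref"]))

    def test_row_without_any_copy_rejected(self):
        anchors = pd.DataFrame([{"gene_a": None, "gene_b": None, "chr_ref": "chr01"}])
        with pytest.raises(ValueError, match="at least one"):
            retention_profile(anchors)


class TestFractionationBias:
    def test_symmetric_losses_give_p_one(self):
        prof = retention_profile(pd.DataFrame(_anchor_rows("chr01", 100, 50, 50)))
        res = fractionation_bias_test(prof)
        assert res["global_p"] == pytest.approx(1.0)

    def test_asymmetric_losses_detected_and_match_direct_summation(self):
        # 75 B-only rows = 75 lost A copies vs 25 lost B copies
        prof = retention_profile(pd.DataFrame(_anchor_rows("chr01", 100, 25, 75)))
        res = fractionation_bias_test(prof)
        assert res["global_p"] < 0.01
        # two-sided exact binomial tail by direct summation
        n, k = 100, 75
        pmf = [math.comb(n, i) * 0.5**n for i in range(n + 1)]
        expected = sum(p for p in pmf if p <= pmf[k] * (1 + 1e-9))
        assert res["global_p"] == pytest.approx(expected, rel=1e-9)

    def test_single_singleton_is_powerless(self):
        prof = retention_profile(pd.DataFrame(_anchor_rows("chr01", 10, 0, 1)))
        res = fractionation_bias_test(prof)
        assert res["global_p"] == pytest.approx(1.0)
        assert res["global_flag"] == "low_power"

    def test_no_singletons_flagged_undefined(self):
        prof = retention_profile(pd.DataFrame(_anchor_rows("chr01", 10, 0, 0)))
        res = fractionation_bias_test(prof)
        assert math.isnan(res["global_p"])
        assert res["global_flag"] == "no_singletons"

    def test_null_pvalues_approximately_uniform(self, rng):
        # exact binomial p-values are discrete, so bound the KS distance
        # rather than demanding a uniformity test pass
        pvals = []
        for _ in range(1000):
            lost_a = rng.binomial(2000, 0.5)
            prof = pd.DataFrame(
                {"lost_a": [lost_a], "lost_b": [2000 - lost_a]}, index=["chr01"]
            )
            pvals.append(fractionation_bias_test(prof)["global_p"])
        grid = np.sort(pvals)
        ks_stat = np.max(np.abs(grid - np.arange(1, 1001) / 1000))
        assert ks_stat < 0.08


def _expr_two_conditions(rng, n_genes, lfc_genes=None, lfc=2.0, noise=0.1, n_rep=4):
    base = rng.normal(6.0, 1.0, n_genes)
    shift = np.zeros(n_genes)
    if lfc_genes is not None:
        shift[lfc_genes] = lfc
    cols = {}
    for r in range(1, n_rep + 1):
        cols[f"control_rep{r}"] = 2 ** (base + rng.normal(0, noise, n_genes))
    for r in range(1, n_rep + 1):
        cols[f"treat_rep{r}"] = 2 ** (base + shift + rng.normal(0, noise, n_genes))
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])


class TestCallDe:
    def test_no_signal_no_calls(self, rng):
        expr = _expr_two_conditions(rng, 300)
        de = call_de(expr, "control", "treat")
        assert de["de"].sum() <= 0.05 * 300  # BH false-positive control

    def test_spiked_genes_recovered(self, rng):
        spiked = np.arange(100)
        expr = _expr_two_conditions(rng, 1000, lfc_genes=spiked, lfc=2.0)
        de = call_de(expr, "control", "treat")
        assert de.iloc[spiked]["de"].sum() >= 95
        false_pos = de.iloc[100:]["de"].sum()
        assert false_pos <= 0.05 * 900
        assert (de.iloc[spiked].loc[de.iloc[spiked]["de"], "direction"] == "up").all()

    def test_fold_change_gate_blocks_sub_twofold(self, rng):
        # strong significance but below the twofold gate
        expr = _expr_two_conditions(rng, 50, lfc_genes=np.arange(50), lfc=np.log2(1.9), noise=0.02)
        de = call_de(expr, "control", "treat")
        assert de["de"].sum() == 0

    def test_missing_condition_rejected(self, rng):
        expr = _expr_two_conditions(rng, 10)
        with pytest.raises(ValueError, match="replicates"):
            call_de(expr, "control", "absent")


class TestHebClassify:
    def test_equal_copies_unbiased(self):
        cols = [f"cond1_rep{r}" for r in range(1, 5)]
        expr = pd.DataFrame(
            {c: [50.0, 50.0] for c in cols}, index=["p1_A", "p1_B"]
        )
        pairs = pd.DataFrame({"pair_id": ["p1"], "gene_a": ["p1_A"], "gene_b": ["p1_B"]})
        calls = heb_classify(expr, pairs)
        assert (calls["call"] == "UNBIASED").all()

    def test_low_expression_untestable(self):
        cols = [f"cond1_rep{r}" for r in range(1, 5)]
        expr = pd.DataFrame({c: [0.1, 0.2] for c in cols}, index=["p1_A", "p1_B"])
        pairs = pd.DataFrame({"pair_id": ["p1"], "gene_a": ["p1_A"], "gene_b": ["p1_B"]})
        assert (heb_classify(expr, pairs)["call"] == "UNTESTABLE").all()

    def test_simulated_bias_recovered(self):
        spec = BiasSpec(n_pairs=2000, frac_b_biased=0.25, effect_log2fc=2.0)
        expr, truth = simulate_expression(spec, seed=9)
        calls = heb_classify(expr, truth)
        frac_b = (calls["call"] == "B_BIASED").mean()
        assert frac_b == pytest.approx(0.25, abs=0.03)

    def test_label_swap_flips_every_directional_call(self):
        spec = BiasSpec(n_pairs=200, frac_b_biased=0.3, frac_a_biased=0.2)
        expr, truth = simulate_expression(spec, seed=10)
        calls = heb_classify(expr, truth)
        swapped = truth.rename(columns={"gene_a": "gene_b", "gene_b": "gene_a"})
        calls_sw = heb_classify(expr, swapped)
        flip = {"A_BIASED": "B_BIASED", "B_BIASED": "A_BIASED",
                "UNBIASED": "UNBIASED", "UNTESTABLE": "UNTESTABLE"}
        assert (calls_sw["call"] == calls["call"].map(flip)).all()
        assert np.allclose(calls_sw["log2_ratio"], -calls["log2_ratio"], atol=1e-12)

    def test_unmapped_pair_rejected(self):
        cols = [f"cond1_rep{r}" for r in range(1, 5)]
        expr = pd.DataFrame({c: [1.0] for c in cols}, index=["p1_A"])
        pairs = pd.DataFrame({"pair_id": ["p1"], "gene_a": ["p1_A"], "gene_b": ["missing"]})
        with pytest.raises(KeyError, match="missing"):
            heb_classify(expr, pairs)

    def test_null_biased_fraction_within_fdr(self):
        spec = BiasSpec(n_pairs=1000, n_conditions=2)
        expr, truth = simulate_expression(spec, seed=11)
        calls = heb_classify(expr, truth)
        biased = calls["call"].isin(["A_BIASED", "B_BIASED"]).mean()
        assert biased <= 0.05


def _calls_fixture(n_b, n_a, n_unbiased, condition="cond1"):
    rows = []
    i = 0
    for call, n in (("B_BIASED", n_b), ("A_BIASED", n_a), ("UNBIASED", n_unbiased)):
        for _ in range(n):
            rows.append(
                {"pair_id": f"p{i}", "condition": condition, "call": call,
                 "log2_ratio": 0.0, "padj": 1.0}
            )
            i += 1
    return pd.DataFrame(rows)


class TestHebSummary:
    def test_printed_percentage_recomputes_exactly(self):
        # 3155 B-biased of 11,861 comparisons -> 26.6 %
        calls = _calls_fixture(3155, 0, 11861 - 3155)
        summary = heb_summary(calls)
        assert summary["n_comparisons"] == 11861
        assert summary["b_biased_pct"] == 26.6

    def test_all_unbiased_zero_fractions(self):
        summary = heb_summary(_calls_fixture(0, 0, 50))
        assert summary["biased_in_any"] == 0
        assert summary["b_biased_pct"] == 0.0

    def test_single_condition_any_equals_all(self):
        summary = heb_summary(_calls_fixture(10, 5, 20))
        assert summary["biased_in_any"] == summary["biased_in_all"] == 15

    def test_counting_identities(self):
        two_cond = pd.concat(
            [_calls_fixture(10, 0, 30, "cond1"), _calls_fixture(4, 0, 36, "cond2")],
            ignore_index=True,
        )
        summary = heb_summary(two_cond)
        assert summary["biased_in_all"] <= summary["biased_in_any"] <= summary["n_pairs"]


def _deg_table(entries):
    return pd.DataFrame(entries, columns=["gene", "treatment", "tissue", "direction"])


class TestConcordance:
    def test_printed_drought_percentage(self):
        # 99 ortholog pairs DE in both species, 52 with identical patterns
        deg1, deg2, orth = [], [], []
        for i in range(99):
            orth.append({"gene_s1": f"s1_{i}", "gene_s2": f"s2_{i}"})
            deg1.append((f"s1_{i}", "drought", "root", "up"))
            deg2.append((f"s2_{i}", "drought", "root", "up" if i < 52 else "down"))
        calls, summary = ortholog_deg_concordance(
            _deg_table(deg1), _deg_table(deg2), pd.DataFrame(orth)
        )
        row = summary.set_index("treatment").loc["drought"]
        assert row["n_pairs"] == 99
        assert row["n_conserved"] == 52
        assert row["conserved_pct"] == 53

    def test_identical_patterns_fully_conserved(self):
        deg = _deg_table([("g1", "heat", "root", "up")])
        deg2 = _deg_table([("h1", "heat", "root", "up")])
        orth = pd.DataFrame({"gene_s1": ["g1"], "gene_s2": ["h1"]})
        _, summary = ortholog_deg_concordance(deg, deg2, orth)
        assert summary["conserved_pct"].iloc[0] == 100

    def test_opposite_directions_divergent(self):
        deg = _deg_table([("g1", "heat", "root", "up")])
        deg2 = _deg_table([("h1", "heat", "root", "down")])
        orth = pd.DataFrame({"gene_s1": ["g1"], "gene_s2": ["h1"]})
        _, summary = ortholog_deg_concordance(deg, deg2, orth)
        assert summary["conserved_pct"].iloc[0] == 0

    def test_same_direction_different_tissue_divergent(self):
        deg = _deg_table([("g1", "cold", "shoot", "up")])
        deg2 = _deg_table([("h1", "cold", "root", "up")])
        orth = pd.DataFrame({"gene_s1": ["g1"], "gene_s2": ["h1"]})
        calls, _ = ortholog_deg_concordance(deg, deg2, orth)
        assert (calls["verdict"] == "DIVERGENT").all()

    def test_pairs_de_in_one_species_excluded(self):
        deg = _deg_table([("g1", "heat", "root", "up")])
        deg2 = _deg_table([])
        orth = pd.DataFrame({"gene_s1": ["g1"], "gene_s2": ["h1"]})
        calls, summary = ortholog_deg_concordance(deg, deg2, orth)
        assert len(calls) == 0

    def test_ortholog_collision_rejected(self):
        orth = pd.DataFrame({"gene_s1": ["g1", "g1"], "gene_s2": ["h1", "h2"]})
        with pytest.raises(ValueError, match="collid"):
            ortholog_deg_concordance(_deg_table([]), _deg_table([]), orth)


class TestTandemDeg:
    def test_printed_percentages(self):
        genes = [f"t{i}" for i in range(1993)]
        # 902 clusters: 236 clusters get two DE genes each (472 DE), the
        # remaining 283 DE genes sit one per cluster
        clusters = []
        gi = 0
        for c in range(902):
            size = 3 if c < 189 else 2
            for _ in range(size):
                clusters.append({"gene": genes[gi], "cluster_id": f"c{c}"})
                gi += 1
        while gi < 1993:
            clusters.append({"gene": genes[gi], "cluster_id": f"c{gi % 902}"})
            gi += 1
        df = pd.DataFrame(clusters).drop_duplicates("gene")
        per_cluster = df.groupby("cluster_id")["gene"].apply(list)
        de = []
        for c in per_cluster.index[:236]:
            de.extend(per_cluster[c][:2])
        for c in per_cluster.index[236:]:
            if len(de) < 755:
                de.append(per_cluster[c][0])
        summary = tandem_deg_summary(df, set(de))
        assert summary["n_tandem_genes"] == 1993
        assert summary["n_de_genes"] == 755
        assert summary["de_gene_pct"] == 37.9
        assert summary["n_clusters"] == 902
        assert summary["n_clusters_multi_de"] == 236
        assert summary["clusters_multi_de_pct"] == 26.2

    def test_no_de_genes(self):
        df = pd.DataFrame({"gene": ["a", "b"], "cluster_id": ["c1", "c1"]})
        summary = tandem_deg_summary(df, set())
        assert summary["n_de_genes"] == 0
        assert summary["clusters_multi_de_pct"] == 0.0

    def test_gene_in_two_clusters_rejected(self):
        df = pd.DataFrame({"gene": ["a", "a"], "cluster_id": ["c1", "c2"]})
        with pytest.raises(ValueError, match="more than one"):
            tandem_deg_summary(df, set())
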