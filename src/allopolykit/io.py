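"""File formats (FASTA, Newick, anchor/expression TSV), run configuration,
and the end-to-end pipeline report."""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_SEQ_RE = re.compile(r"^[ACGTUN\-]+$")

ANCHOR_COLUMNS = ["ref_gene", "gene_a", "gene_b", "chr_ref", "chr_a", "chr_b", "block_id", "status"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> uppercase sequence mapping."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not _SEQ_RE.match(seq):
            bad = sorted(set(seq) - set("ACGTUN-"))
            raise ValueError(f"record {rec.id!r}: illegal characters {bad}")
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# Newick

def read_newick(path: str | Path) -> list[dendropy.Tree]:
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    if len(trees) == 0:
        raise ValueError(f"no trees in {path}")
    return list(trees)


def write_newick(trees, path: str | Path) -> None:
    lines = []
    for t in trees:
        if isinstance(t, dendropy.Tree):
            s = t.as_string(schema="newick", suppress_rooting=True).strip()
        else:
            s = str(t).strip()
            if not s.endswith(";"):
                s += ";"
        lines.append(s)
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# anchor tables

def read_anchors(path: str | Path, chromosomes: set[str] | None = None) -> pd.DataFrame:
    """Read an anchor TSV ('.' or empty = absent copy) into an AnchorTable."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"gene_a", "gene_b"} - set(df.columns)
    if missing:
        raise ValueError(f"anchor table {path} lacks columns {sorted(missing)}")
    for col in ("gene_a", "gene_b", "chr_a", "chr_b"):
        if col in df.columns:
            df[col] = df[col].replace({".": None, "": None})
    both_absent = df["gene_a"].isna() & df["gene_b"].isna()
    if both_absent.any():
        line = int(both_absent.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}:{line}: both subgenome copies absent")
    if chromosomes is not None and "chr_ref" in df.columns:
        unknown = set(df["chr_ref"].dropna()) - chromosomes
        if unknown:
            raise ValueError(f"unknown chromosome labels {sorted(unknown)}")
    return df


def write_anchors(anchors: pd.DataFrame, path: str | Path) -> None:
    out = anchors.copy()
    for col in ("gene_a", "gene_b", "chr_a", "chr_b"):
        if col in out.columns:
            out[col] = out[col].fillna(".")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression tables

def read_expression(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"negative TPM values in {path}")
    return df


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# run configuration and pipeline

@dataclass
class RunConfig:
    """Thresholds and sizes for an end-to-end simulated run."""

    seed: int = 0
    out_dir: str = "allopolykit_run"
    # scenario
    wgd_mode: str = "SHARED"
    t_wgd: float = 18.19
    t_speciation: float = 10.0
    rate_r: float = 6.5e-9
    omega: float = 0.2
    n_codons: int = 1000
    # sizes
    n_quartets: int = 100
    n_anchors: int = 5000
    n_ltr: int = 200
    ltr_time_ma: float = 0.8
    ltr_rate_r: float = 1.3e-8
    n_expression_pairs: int = 500
    frac_b_biased: float = 0.0
    # thresholds
    ks_cap: float = 3.0
    fc_threshold: float = 2.0
    fdr: float = 0.05
    alpha: float = 0.05
    min_effect: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Simulate every input type and run the full analysis stack on it.

    Stages: quartet simulation -> gene trees -> shared-WGD support;
    sequence-pair Ks at the two event times -> mixture peaks -> dating;
    fractionation simulation -> retention and bias test; expression
    simulation -> HEB classification and summary; LTR simulation ->
    insertion-time estimates. Writes ``report.json`` (with seed and config
    hash) plus per-stage TSVs under ``out_dir``.
    """
    from . import __version__, dating, homoeolog, ks, ploidy, simulate

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": "allopolykit",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "stages": {},
    }

    def _stage(name):
        report["stages"][name] = {}
        return report["stages"][name]

    # 1. quartets -> topology support
    scen = simulate.ScenarioConfig(
        wgd_mode=config.wgd_mode,
        t_wgd=config.t_wgd,
        t_speciation=config.t_speciation,
        rate_r=config.rate_r,
        omega=config.omega,
        n_codons=config.n_codons,
        seed=config.seed,
    )
    quartets = simulate.simulate_quartets(scen, config.n_quartets)
    calls = [ploidy.quartet_topology(q.sequences, q.gene_id) for q in quartets]
    support = ploidy.shared_wgd_support(calls)
    pd.DataFrame(
        {"gene_id": [c.gene_id for c in calls], "call": [c.call.value for c in calls]}
    ).to_csv(out / "topology_calls.tsv", sep="\t", index=False)
    _stage("quartet_test").update(support)

    # 2. Ks distributions at the two event times -> peaks -> dating
    rng = simulate._stream(config.seed, "pair")
    cal = dating.RateCalibration(config.rate_r, source="simulation truth")
    t_wgd = max(config.t_wgd) if isinstance(config.t_wgd, (list, tuple)) else config.t_wgd
    ks_young, ks_old = [], []
    for _ in range(150):
        for t, sink in ((config.t_speciation, ks_young), (t_wgd, ks_old)):
            a, b = simulate.simulate_sequence_pair(t, scen, rng=rng)
            res = ks.compute_ka_ks(a, b)
            if res.usable and res.ks is not None:
                sink.append(res.ks)
    peaks = ks.fit_ks_peaks(ks_young + ks_old, k_max=3, seed=config.seed, ks_cap=config.ks_cap)
    stage = _stage("ks_peaks")
    stage["k"] = peaks.k
    stage["means"] = list(peaks.means)
    stage["dated_ma"] = [dating.divergence_time(m, cal) for m in peaks.means]

    # 3. allo/auto asymmetry on the two cohorts
    asym = ploidy.allo_auto_test(
        ks_young, ks_old, alpha=config.alpha, min_effect=config.min_effect
    )
    _stage("allo_auto_test").update(
        {
            "verdict": asym.verdict.value,
            "p_value": asym.p_value,
            "delta_mode": asym.delta_mode,
        }
    )

    # 4. fractionation
    anchors = simulate.simulate_fractionation(
        config.n_anchors, loss_a=0.2, loss_b=0.2, seed=config.seed
    )
    write_anchors(anchors, out / "anchors.tsv")
    profile = homoeolog.retention_profile(anchors)
    frac = homoeolog.fractionation_bias_test(profile)
    _stage("fractionation").update(
        {
            "global_lost_a": frac["global_lost_a"],
            "global_lost_b": frac["global_lost_b"],
            "global_p": frac["global_p"],
        }
    )

    # 5. homoeolog expression bias
    bias_spec = simulate.BiasSpec(
        n_pairs=config.n_expression_pairs, frac_b_biased=config.frac_b_biased
    )
    expr, truth = simulate.simulate_expression(bias_spec, seed=config.seed)
    write_expression(expr, out / "expression.tsv")
    heb = homoeolog.heb_classify(
        expr, truth, fc_threshold=config.fc_threshold, fdr=config.fdr
    )
    heb_sum = homoeolog.heb_summary(heb)
    heb_sum.pop("per_condition")
    _stage("heb").update(heb_sum)

    # 6. LTR dating
    ltr_cal = dating.RateCalibration(config.ltr_rate_r, source="simulation truth")
    ltrs = simulate.simulate_ltr_pairs(
        config.n_ltr, [config.ltr_time_ma], config.ltr_rate_r, seed=config.seed
    )
    ages = [
        dating.ltr_insertion_time(p.seq_5p, p.seq_3p, ltr_cal) for p in ltrs
    ]
    ages = [a for a in ages if a is not None]
    _stage("ltr_dating").update(
        {
            "n": len(ages),
            "mean_ma": float(pd.Series(ages).mean()),
            "mode_ma": ploidy._kde_mode(pd.Series(ages).to_numpy()),
        }
    )

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
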