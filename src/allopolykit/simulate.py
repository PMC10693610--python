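"""Synthetic data with known ground truth for every analysis stage.

The generator emulates the data types the downstream modules consume:

* coding-sequence quartets (A1, A2, B1, B2 plus outgroup) evolved under a
  shared-allotetraploidy or independent-duplication scenario,
* replicate coding-sequence pairs with a known expected Ks = 2·r·t,
* TPM expression matrices with a controllable fraction of subgenome-biased
  homoeolog pairs,
* syntenic anchor tables with per-subgenome gene-loss (fractionation) rates,
* 5'/3' LTR pairs with known insertion times.

Sequences evolve codon-by-codon: mutation events propose a uniform random
single-nucleotide change; synonymous proposals are always accepted,
nonsynonymous ones with probability omega, stop-creating ones never. The
proposal intensity is scaled so each branch accrues an expected r·t
synonymous substitutions per synonymous site, making the synonymous clock
of the simulated data match the K = 2·r·T identity used for dating (two
tips separated by time t diverge by 2rt). Times are Ma; rates are
substitutions per site per year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codon import AA, CODONS, NUCLEOTIDES, SENSE_CODONS, CODON_INDEX

YEARS_PER_MA = 1e6

WGD_SHARED = "SHARED"
WGD_INDEPENDENT = "INDEPENDENT"

QUARTET_LABELS = ("A1", "A2", "B1", "B2", "OUT")

_STREAM_CODES = {
    "quartets": 1,
    "pair": 2,
    "expression": 3,
    "fractionation": 4,
    "ltr": 5,
}


def _stream(seed: int, op: str) -> np.random.Generator:
    """Per-operation RNG stream derived from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM_CODES[op],))
    )


# ---------------------------------------------------------------------------
# codon-level substitution machinery (precomputed integer tables)

_N_CODON = len(CODONS)
# neighbor codon index for (codon, position, alternative) proposals
_NEIGHBOR = np.zeros((_N_CODON, 3, 3), dtype=np.int64)
# 0 = synonymous, 1 = nonsynonymous, 2 = creates a stop codon
_PROPOSAL_CLASS = np.zeros((_N_CODON, 3, 3), dtype=np.int64)
for _ci, _codon in enumerate(CODONS):
    for _pos in range(3):
        _alts = [nt for nt in NUCLEOTIDES if nt != _codon[_pos]]
        for _ai, _nt in enumerate(_alts):
            _nb = _codon[:_pos] + _nt + _codon[_pos + 1 :]
            _NEIGHBOR[_ci, _pos, _ai] = CODON_INDEX[_nb]
            if AA[_nb] == "*":
                _PROPOSAL_CLASS[_ci, _pos, _ai] = 2
            elif AA[_nb] == AA[_codon]:
                _PROPOSAL_CLASS[_ci, _pos, _ai] = 0
            else:
                _PROPOSAL_CLASS[_ci, _pos, _ai] = 1

_SENSE_IDX = np.array([CODON_INDEX[c] for c in SENSE_CODONS], dtype=np.int64)
_CODON_ARR = np.array(CODONS)


def _random_cds(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(_SENSE_IDX, size=n_codons)


def _evolve(codons: np.ndarray, d_syn: float, omega: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve a codon-index array along a branch of d_syn syn subs / syn site.

    A proposal intensity of 3·L·d_syn uniform events yields an expected
    d_syn accepted synonymous substitutions per NG86 synonymous site.
    """
    seq = codons.copy()
    if d_syn <= 0:
        return seq
    n_events = rng.poisson(3.0 * seq.size * d_syn)
    if n_events == 0:
        return seq
    which = rng.integers(0, seq.size, size=n_events)
    pos = rng.integers(0, 3, size=n_events)
    alt = rng.integers(0, 3, size=n_events)
    accept_u = rng.random(n_events)
    for w, p, a, u in zip(which, pos, alt, accept_u):
        cur = seq[w]
        cls = _PROPOSAL_CLASS[cur, p, a]
        if cls == 2:
            continue
        if cls == 1 and u >= omega:
            continue
        seq[w] = _NEIGHBOR[cur, p, a]
    return seq


def _to_str(codons: np.ndarray) -> str:
    return "".join(_CODON_ARR[codons])


# ---------------------------------------------------------------------------
# scenarios and quartets

@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth evolutionary scenario for quartet/pair simulation.

    SHARED: one allotetraploidy in the common ancestor — the two parental
    subgenome lineages diverged at ``t_wgd``, the A/B species split at the
    younger ``t_speciation``. INDEPENDENT: the species split at
    ``t_speciation`` and each lineage duplicated later, at ``t_wgd``
    (a scalar applied to both lineages, or a ``(t_a, t_b)`` pair).
    """

    wgd_mode: str = WGD_SHARED
    t_wgd: float | tuple[float, float] = 18.19
    t_speciation: float = 10.0
    rate_r: float = 6.5e-9
    omega: float = 0.2
    n_codons: int = 300
    seed: int = 0

    def _wgd_times(self) -> tuple[float, float]:
        if isinstance(self.t_wgd, (tuple, list)):
            if self.wgd_mode != WGD_INDEPENDENT or len(self.t_wgd) != 2:
                raise ValueError("per-lineage t_wgd pair is only valid in INDEPENDENT mode")
            return float(self.t_wgd[0]), float(self.t_wgd[1])
        return float(self.t_wgd), float(self.t_wgd)

    def validate(self) -> None:
        if self.wgd_mode not in (WGD_SHARED, WGD_INDEPENDENT):
            raise ValueError(f"unknown wgd_mode {self.wgd_mode!r}")
        ta, tb = self._wgd_times()
        if min(ta, tb) <= 0 or self.t_speciation <= 0:
            raise ValueError("all event times must be positive")
        if not self.rate_r > 0:
            raise ValueError(f"rate_r must be positive, got {self.rate_r}")
        if not 0 <= self.omega <= 1:
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")
        if self.n_codons <= 0:
            raise ValueError("n_codons must be positive")
        if self.wgd_mode == WGD_SHARED and not ta > self.t_speciation:
            raise ValueError("SHARED scenario requires t_wgd > t_speciation")
        if self.wgd_mode == WGD_INDEPENDENT and not max(ta, tb) < self.t_speciation:
            raise ValueError("INDEPENDENT scenario requires t_wgd < t_speciation")

    def d_syn(self, duration_ma: float) -> float:
        """Expected synonymous divergence accrued on one branch of given length."""
        return self.rate_r * duration_ma * YEARS_PER_MA

    @property
    def t_outgroup(self) -> float:
        """Outgroup divergence: twice the oldest in-group event (rootable)."""
        ta, tb = self._wgd_times()
        return 2.0 * max(ta, tb, self.t_speciation)


@dataclass(frozen=True)
class SimulatedQuartet:
    gene_id: str
    sequences: dict[str, str]
    true_topology: str


def simulate_quartets(config: ScenarioConfig, n_genes: int) -> list[SimulatedQuartet]:
    """Evolve ``n_genes`` five-taxon gene families under the configured scenario."""
    config.validate()
    rng = _stream(config.seed, "quartets")
    om = config.omega
    t_out = config.t_outgroup
    ta, tb = config._wgd_times()
    out: list[SimulatedQuartet] = []
    for g in range(n_genes):
        root = _random_cds(config.n_codons, rng)
        seq_out = _evolve(root, config.d_syn(t_out), om, rng)
        if config.wgd_mode == WGD_SHARED:
            # root(t_out) -> WGD ancestor(t_wgd) -> two subgenome lineages,
            # each splitting into its A and B species copy at t_speciation
            anc = _evolve(root, config.d_syn(t_out - ta), om, rng)
            lin1 = _evolve(anc, config.d_syn(ta - config.t_speciation), om, rng)
            lin2 = _evolve(anc, config.d_syn(ta - config.t_speciation), om, rng)
            d_tip = config.d_syn(config.t_speciation)
            tips = {
                "A1": _evolve(lin1, d_tip, om, rng),
                "B1": _evolve(lin1, d_tip, om, rng),
                "A2": _evolve(lin2, d_tip, om, rng),
                "B2": _evolve(lin2, d_tip, om, rng),
            }
        else:
            # root(t_out) -> speciation(t_speciation) -> per-species WGD
            anc = _evolve(root, config.d_syn(t_out - config.t_speciation), om, rng)
            anc_a = _evolve(anc, config.d_syn(config.t_speciation - ta), om, rng)
            anc_b = _evolve(anc, config.d_syn(config.t_speciation - tb), om, rng)
            tips = {
                "A1": _evolve(anc_a, config.d_syn(ta), om, rng),
                "A2": _evolve(anc_a, config.d_syn(ta), om, rng),
                "B1": _evolve(anc_b, config.d_syn(tb), om, rng),
                "B2": _evolve(anc_b, config.d_syn(tb), om, rng),
            }
        tips["OUT"] = seq_out
        out.append(
            SimulatedQuartet(
                gene_id=f"gene{g:05d}",
                sequences={lab: _to_str(tips[lab]) for lab in QUARTET_LABELS},
                true_topology=config.wgd_mode,
            )
        )
    return out


def simulate_sequence_pair(
    t_ma: float, config: ScenarioConfig, rng: np.random.Generator | None = None
) -> tuple[str, str]:
    """A pair of coding sequences whose expected Ks is 2·r·t (pre-saturation)."""
    if t_ma < 0:
        raise ValueError(f"divergence time must be >= 0, got {t_ma}")
    if not config.rate_r > 0:
        raise ValueError("rate_r must be positive")
    if rng is None:
        rng = _stream(config.seed, "pair")
    root = _random_cds(config.n_codons, rng)
    d = config.d_syn(t_ma)
    a = _evolve(root, d, config.omega, rng)
    b = _evolve(root, d, config.omega, rng)
    return _to_str(a), _to_str(b)


# ---------------------------------------------------------------------------
# expression with homoeolog bias ground truth

@dataclass(frozen=True)
class BiasSpec:
    """Ground-truth design of a homoeolog expression-bias simulation."""

    n_pairs: int = 2000
    frac_b_biased: float = 0.0
    frac_a_biased: float = 0.0
    effect_log2fc: float = 2.0
    dispersion: float = 0.25
    n_conditions: int = 8
    n_replicates: int = 4
    base_log2_mean: float = 5.6
    base_log2_sd: float = 1.5

    def validate(self) -> None:
        if self.n_pairs <= 0:
            raise ValueError("n_pairs must be positive")
        for name in ("frac_b_biased", "frac_a_biased"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_a_biased + self.frac_b_biased > 1:
            raise ValueError("biased fractions must sum to <= 1")
        if self.effect_log2fc <= 0 or self.dispersion <= 0:
            raise ValueError("effect_log2fc and dispersion must be positive")
        if self.n_conditions < 1 or self.n_replicates < 2:
            raise ValueError("need >= 1 condition and >= 2 replicates")


def simulate_expression(spec: BiasSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal TPM matrix plus truth labels per homoeolog pair.

    Biased pairs have their two copies' log2 means split by
    ``effect_log2fc`` toward the designated subgenome, identically in all
    conditions; unbiased pairs share means. Returns (expression, truth)
    where expression rows are ``pair####_A`` / ``pair####_B`` and columns
    ``cond#_rep#``, and truth has columns pair_id, gene_a, gene_b, bias
    ('A', 'B' or 'none').
    """
    spec.validate()
    rng = _stream(seed, "expression")
    n = spec.n_pairs
    n_b = int(round(spec.frac_b_biased * n))
    n_a = int(round(spec.frac_a_biased * n))
    bias = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    bias[order[:n_b]] = "B"
    bias[order[n_b : n_b + n_a]] = "A"

    base = rng.normal(spec.base_log2_mean, spec.base_log2_sd, size=n)
    shift = np.where(bias == "B", spec.effect_log2fc / 2.0, np.where(bias == "A", -spec.effect_log2fc / 2.0, 0.0))
    mean_a = base - shift
    mean_b = base + shift

    pair_ids = [f"pair{i:04d}" for i in range(n)]
    genes_a = [f"{p}_A" for p in pair_ids]
    genes_b = [f"{p}_B" for p in pair_ids]
    columns = [
        f"cond{c}_rep{r}" for c in range(1, spec.n_conditions + 1) for r in range(1, spec.n_replicates + 1)
    ]
    n_samples = len(columns)
    log_a = mean_a[:, None] + rng.normal(0.0, spec.dispersion, size=(n, n_samples))
    log_b = mean_b[:, None] + rng.normal(0.0, spec.dispersion, size=(n, n_samples))
    expr = pd.DataFrame(
        np.vstack([np.power(2.0, log_a), np.power(2.0, log_b)]),
        index=genes_a + genes_b,
        columns=columns,
    )
    truth = pd.DataFrame(
        {"pair_id": pair_ids, "gene_a": genes_a, "gene_b": genes_b, "bias": bias}
    )
    return expr, truth


# ---------------------------------------------------------------------------
# fractionation (anchor tables with gene loss)

def simulate_fractionation(
    n_anchors: int,
    loss_a: float,
    loss_b: float,
    n_chromosomes: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Anchor table where each ancestral gene loses its A copy with
    probability ``loss_a`` and its B copy with ``loss_b`` — never both
    (joint losses are redrawn, conditioning on at least one surviving copy).
    """
    for name, p in (("loss_a", loss_a), ("loss_b", loss_b)):
        if not 0 <= p < 1:
            raise ValueError(f"{name} must be in [0, 1), got {p}")
    if n_anchors <= 0 or n_chromosomes <= 0:
        raise ValueError("n_anchors and n_chromosomes must be positive")
    rng = _stream(seed, "fractionation")
    lose_a = rng.random(n_anchors) < loss_a
    lose_b = rng.random(n_anchors) < loss_b
    both = lose_a & lose_b
    while both.any():
        k = int(both.sum())
        lose_a[both] = rng.random(k) < loss_a
        lose_b[both] = rng.random(k) < loss_b
        both = lose_a & lose_b

    idx = np.arange(n_anchors)
    chrom = idx * n_chromosomes // n_anchors + 1
    status = np.where(lose_a, "b_only", np.where(lose_b, "a_only", "pair"))
    df = pd.DataFrame(
        {
            "ref_gene": [f"Ref_g{i:05d}" for i in idx],
            "gene_a": [None if la else f"SubA_g{i:05d}" for i, la in zip(idx, lose_a)],
            "gene_b": [None if lb else f"SubB_g{i:05d}" for i, lb in zip(idx, lose_b)],
            "chr_ref": [f"chr{c:02d}" for c in chrom],
            "chr_a": [f"A{c:02d}" for c in chrom],
            "chr_b": [f"B{c:02d}" for c in chrom],
            "block_id": [f"block{c:02d}" for c in chrom],
            "status": status,
        }
    )
    return df


# ---------------------------------------------------------------------------
# LTR pairs with known insertion times

@dataclass(frozen=True)
class SimulatedLtrPair:
    ltr_id: str
    seq_5p: str
    seq_3p: str
    true_time_ma: float


def simulate_ltr_pairs(
    n: int,
    insertion_times: list[float],
    rate_r: float,
    seed: int = 0,
    ltr_length: int = 1000,
) -> list[SimulatedLtrPair]:
    """5'/3' LTR pairs diverged so that expected K = 2·r·t per pair.

    ``insertion_times`` (Ma) is used directly if it has length ``n``,
    otherwise times are drawn from it with replacement. The two LTRs start
    identical at insertion and each accumulates r·t substitutions per site
    under a Jukes–Cantor process.
    """
    times = np.asarray(insertion_times, dtype=float)
    if times.size == 0 or (times < 0).any():
        raise ValueError("insertion times must be non-empty and >= 0")
    if not rate_r > 0:
        raise ValueError("rate_r must be positive")
    rng = _stream(seed, "ltr")
    if times.size != n:
        times = rng.choice(times, size=n)

    nts = np.frombuffer(b"ACGT", dtype="S1")
    out: list[SimulatedLtrPair] = []
    for i, t in enumerate(times):
        anc = rng.integers(0, 4, size=ltr_length)
        d = rate_r * t * YEARS_PER_MA
        pair_seqs = []
        for _ in range(2):
            seq = anc.copy()
            n_events = rng.poisson(ltr_length * d)
            if n_events:
                sites = rng.integers(0, ltr_length, size=n_events)
                steps = rng.integers(1, 4, size=n_events)
                for s, st in zip(sites, steps):
                    seq[s] = (seq[s] + st) % 4
            pair_seqs.append(nts[seq].tobytes().decode())
        out.append(SimulatedLtrPair(f"ltr{i:05d}", pair_seqs[0], pair_seqs[1], float(t)))
    return out
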