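# Methods

## Ka/Ks by Nei–Gojobori counting

The engine implements the classical NG86 procedure on in-frame pairwise
alignments:

* **Sites.** Each sense codon contributes ⅓ synonymous site per synonymous
  single-nucleotide neighbor (9 neighbors per codon), nonsynonymous sites
  being the complement so that every counted codon contributes exactly
  3 sites. Mutations that would create a stop codon are counted as
  nonsynonymous sites — this keeps the conservation identity
  *n* + *s* = 3 × (comparable codons) exact, which the test suite asserts
  on every input. Codons containing `N` or gaps, and stop codons, are
  skipped symmetrically in both sequences.
* **Differences.** Between two codons, all minimal mutational pathways are
  enumerated; pathways passing through a stop codon are discarded (with a
  fallback to all pathways in the rare case every pathway is blocked), and
  synonymous/nonsynonymous step counts are averaged over the remaining
  pathways.
* **Correction.** pS = Sd/S and pN = Nd/N are Jukes–Cantor corrected,
  d = −¾ ln(1 − 4p/3). The correction is undefined at p ≥ ¾; such pairs are
  flagged saturated and their distance reported as undefined rather than
  clamped. Pairs with fewer than 30 comparable codons are flagged unusable
  and carry counts but no distances.

Only the standard nuclear genetic code is wired in (the code table is
derived from Biopython's, so counting and simulation cannot disagree on
what synonymous means). No gamma rate variation and no
transition/transversion weighting: equal pathway weighting is the original
NG86 choice and is what the common synteny-pipeline Ks scripts compute,
which keeps this engine's output comparable with published Ks
distributions.

## Ks distributions and peaks

Per-block summaries average usable, unsaturated pairs (mean by default —
the conventional "average Ks of a syntenic block" — median selectable);
blocks with fewer than 5 usable pairs are flagged. Distribution analysis
filters Ks to (0, 3.0] by default: beyond Ks ≈ 3 the Jukes–Cantor
correction regime is dominated by saturation noise and contributes no
dating signal. Peaks are Gaussian mixtures fitted by EM for k = 1..k_max,
each from 10 seeded k-means initializations, with k selected by BIC (ties
toward smaller k). Constant-valued or tiny (< 50 values) inputs are
rejected rather than fitted.

## Dating

T = K / 2r, with r in substitutions per site per year and T reported in
Ma. The factor 2 is the two lineages separating a sequence pair; the same
formula dates LTR retrotransposon insertions, since the 5′ and 3′ LTRs are
identical at insertion and diverge afterwards like any pair. LTR K is the
Jukes–Cantor distance over unambiguous columns; saturated pairs (p ≥ ¾)
are reported undefined. `calibrate_rate` is the exact inverse (r = K/2T)
and round-trips to machine precision.

No default r is baked in: rates differ by lineage and by genomic
compartment, so every dating call takes an explicit `RateCalibration`. The
simulations and examples use 6.5 × 10⁻⁹ synonymous substitutions/site/year
for coding sequence (the widely used grass synonymous rate) and
1.3 × 10⁻⁸/site/year for LTRs (a typical intergenic rate — and the rate at
which K = 0.26 dates to 10 Ma).

## Quartet topology test

Gene trees are built from Jukes–Cantor distance matrices by
neighbor-joining (deterministic: Q-criterion ties break toward the
smallest taxon-index pair), or imported as Newick from external ML tools.
Classification roots at the outgroup and requires it to sit on the central
edge: a supporting tree is two in-group cherries, {Ai,Bj} with {Ak,Bl}
for a shared duplication, {A1,A2} with {B1,B2} for independent
duplications. Both cross-species pairings count as shared — copy indices
within a subgenome are arbitrary, and the biological hypothesis is "each A
copy sisters a B copy", not a particular indexing. Trees where the
outgroup nests inside the in-group, and multifurcations, are OTHER: they
support neither history, mirroring how gene-tree counting pipelines score
only trees matching the reference topology. No bootstrap-support filter is
applied by default (imported trees keep their support values, so callers
can filter upstream).

## Ks-asymmetry (allo vs auto) test

Two Ks samples (reference chromosome vs each duplicate) are compared with
a two-sided Mann–Whitney test plus |Δmode| estimated by Gaussian-KDE mode
finding. Verdicts: ALLO_CONSISTENT requires p < α **and** |Δmode| ≥
min_effect; AUTO_CONSISTENT requires neither; anything mixed, or either
sample under 20 usable values, is INCONCLUSIVE. Defaults α = 0.05 and
min_effect = 0.05 Ks units: the underlying argument in genome papers is
usually made visually from dotplot Ks coloring, so the explicit thresholds
here are this package's formalization — both are configurable. The
compound rule makes the test conservative (measured null type-I error is
well under α).

## Fractionation and expression analyses

* **Fractionation.** Among singleton anchors (one subgenome copy lost), an
  exact binomial test of A-losses vs B-losses against 0.5, per reference
  chromosome (BH-corrected) and pooled. Chromosomes without singletons are
  flagged undefined; fewer than 10 singletons is flagged low-power.
* **Differential expression.** Welch t-test on log2(TPM+1) with pseudocount
  1, BH correction, DE iff |log2FC| ≥ 1 and adjusted p < 0.05. This is a
  deliberate, declared simplification of count-based negative-binomial DE
  models: it needs only TPM matrices, and the concordance/tandem summaries
  accept externally produced DE tables wherever a count-based engine is
  preferred.
* **HEB.** The same test applied A-copy vs B-copy within each condition; a
  pair is testable in a condition if either copy reaches TPM ≥ 1,
  UNTESTABLE otherwise; BH runs within condition across testable pairs.
  "Biased in all conditions" requires a consistent direction across all
  conditions (direction-free counting can be recovered from the per-call
  table if wanted).
* **Concordance.** Orthologs DE in both species under a treatment are
  CONSERVED iff their (shoot, root) direction patterns match exactly,
  including shared non-significance per tissue. Conserved percentages are
  reported rounded to integers; fractionation/HEB/tandem percentages to
  one decimal — matching how such numbers are conventionally reported.

## Synthetic-data generator

The generator is the package's ground-truth instrument, not a genome
simulator. Choices and limits:

* **Sequence evolution.** Codon-wise proposal process: uniform random
  single-nucleotide proposals accepted with probability 1 if synonymous,
  ω if nonsynonymous (default ω = 0.2, typical purifying selection), 0 if
  stop-creating. Proposal intensity is scaled so a branch of duration t
  accrues an expected r·t accepted synonymous substitutions per NG86
  synonymous site; a pair separated by time t therefore has E[Ks] ≈ 2rt
  pre-saturation, which the Monte-Carlo tests verify (mean Ks within
  ±0.02 of 2rt = 0.2 at 5,000 codons × 200 replicates). No indels, no
  recombination, no rate heterogeneity across sites or lineages, no
  incomplete lineage sorting — so classifier accuracies measured here are
  upper bounds for real data, where ILS and alignment error inflate the
  OTHER class.
* **Scenario trees.** SHARED: parental subgenomes diverge at t_wgd, species
  split at t_speciation < t_wgd. INDEPENDENT: species split first, each
  lineage duplicates at t_wgd < t_speciation (optionally per-lineage
  times). The outgroup diverges at twice the oldest in-group event,
  guaranteeing rootability. Default times 18.19/10 Ma with
  r = 6.5 × 10⁻⁹/site/year give Ks ≈ 0.24/0.13 — comfortably
  pre-saturation with clean mixture separation.
* **Expression.** Log-normal TPM (base log2 mean 5.6, SD 1.5 across pairs;
  replicate noise SD 0.25 in log2), 8 conditions × 4 replicates by default
  (five tissues plus three stress treatments, four biological replicates —
  the design of typical polyploid expression atlases). Biased pairs have
  their copies' means split symmetrically by effect_log2fc in every
  condition; real homoeolog bias is often condition-specific, which this
  deliberately idealizes.
* **Fractionation.** Per-anchor independent loss with probabilities
  (loss_a, loss_b), conditioned on at least one copy surviving (joint
  losses are redrawn), anchors assigned contiguously to chromosomes.
* **LTR pairs.** Jukes–Cantor nucleotide process on 1 kb LTRs, each copy
  accruing r·t substitutions/site. At 0.8 Ma and r = 1.3 × 10⁻⁸ a single
  pair's age estimate has SD ≈ 0.2 Ma from Poisson noise alone; cohort
  modes are recovered within ±0.1 Ma at n = 500.
* **Determinism.** One global seed feeds per-operation independent RNG
  streams (numpy `SeedSequence` spawn keys), so identical seed + config
  reproduce outputs byte-identically and operations cannot contaminate one
  another's streams.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen for sharp statistical
resolution at interactive runtimes: 1,000 random 30-codon pairs for oracle
agreement (tolerance 1e-9), 200 quartets × 2,000 codons per scenario
(≥ 95 % recovery), 2,000-draw mixtures (means within ±0.02), 500-pair LTR
cohorts (mode within ±0.1 Ma), and 1,000-replicate null calibrations for
the asymmetry and HEB tests. Headline percentages from full-genome studies
(tens of thousands of gene pairs) are validated as exact recomputations
from their printed numerator/denominator counts, not re-derived from raw
data.

## Known limitations

* NG86 with Jukes–Cantor correction underestimates Ks relative to
  ML codon models (YN00/GY94) at high divergence and ignores
  transition/transversion bias; fine for peak dating below Ks ≈ 1.5, not
  for absolute ω inference.
* The LTR clock uses the Jukes–Cantor correction; classic pipelines often
  apply other distance dialects (e.g. K80), a difference of a few percent
  at these divergences.
* NJ gene trees have no branch-support notion; for publication-grade
  counts, import ML trees and use the classifier on them.
* The DE engine assumes roughly log-normal TPM with ≥ 2 (ideally 4)
  replicates; at very low expression its calls are less reliable than
  count-based negative-binomial models, which can be plugged in via
  external DE tables.
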