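# Methods

## Problem setting

Phosphoproteomes from several closely related species, each measured
incompletely, are compared to find the phosphosites that evolution has
preserved. The pipeline treats three intertwined inference problems:
(1) is a site's sequence neighborhood conserved across orthologs, (2) how
likely is an *unobserved* acceptor to be genuinely phosphorylated, and
(3) how much does each species' catalog miss. All protein positions are
1-based; alignment columns likewise.

## Conservation scoring

A site is summarized by its window: the acceptor plus `flank = 5` residues
each side, nominal length 11. Window identity between the reference and an
ortholog is the count of position-wise identical residues divided by the
**nominal** length, so one mismatch gives 10/11 ≈ 0.909 (displayed as 0.9;
comparisons always use the unrounded value). Three deliberate choices:

- The denominator stays 11 even when a window is clipped at a protein
  terminus; missing positions count as mismatches. This keeps scores
  comparable across sites instead of inflating terminal ones.
- The unknown residue `X` never matches anything, including another `X`.
- An ortholog with a gap at the acceptor column contributes similarity 0
  rather than being excluded: absence of the site is the strongest
  non-conservation signal, and exclusion would bias averages upward.

A site's average similarity is the arithmetic mean of reference-vs-ortholog
identities (an all-species-pairs mean is available via
`pairing="all_pairs"`). Sites with average similarity strictly greater
than 0.5 are called conserved. Acceptor fate per ortholog is classified as
identical / class-changed / lost / gap; by default only S↔T substitutions
count as a class change (`acceptor_class="broad"` relaxes this to any
S/T/Y interchange), because tyrosine kinases are mechanistically distinct
from S/T kinases.

## Phosphorylation propensity

Each window is scored against a bank of 40 position-specific scoring
matrices spanning the kinase archetypes seen in metazoan phosphoproteomes
(proline-directed, basophilic, acidophilic for S/T; acidic/hydrophobic
motifs for Y). Feature *k* is the sum of PSSM *k*'s weights over the
window; clipped positions and non-standard residues contribute 0. The bank
ships as a sparse TSV (only non-zero cells) under
`src/phosite_evo/data/`; users can substitute their own.

Positives are MS-detected sites; negatives are acceptors never detected in
any source. Up to 2000 S/T and 800 Y windows per class are sampled without
replacement. Negative-set contamination by real-but-undetected sites is
acknowledged and uncorrected — it bounds achievable discrimination but
matches how such models are trained in practice. S and T are pooled into
one model; Y gets its own.

The classifier is a linear maximum-margin fit: full-batch subgradient
descent on L2-regularized hinge loss, λ = 1e-3, 500 iterations, step
1/(λt), zero initialization, unregularized bias. It is deterministic by
construction — identical data and seed give bitwise-identical weights.
Margins are mapped to [0, 1] by a two-parameter logistic (Platt) fit on the
training margins. Observed sites bypass the model entirely and score
exactly 1.

## False-negative rates

Benchmark sites are aligned sites whose 11-mer windows are 100% identical
across *all* species (hence gap-free and untruncated) and that were
observed in ≥ 2 species; such sites are almost certainly phosphorylated
everywhere, so the fraction a species misses estimates its FNR. Because a
species' own detections help a site qualify, the naive ratio slightly
underestimates the marginal miss probability; the recovery analysis
therefore compares against the conditional expectation
P(missed | ≥ 2 detections), computed exactly by enumerating the 2⁶
detection patterns. Wilson 95% intervals accompany point estimates.

## Enrichment statistics

The two-sided Fisher exact test uses the probability-mass rule: the
p-value sums hypergeometric probabilities of all tables (same margins) no
more probable than the observed one. It is computed in exact integer
arithmetic — numerators C(r₁,a)·C(r₂,c) share one denominator, so the
"no more probable" comparison is between integers and immune to
floating-point tie ambiguity; the single division to a float happens last.
A zero margin yields p = 1 by convention. The odds ratio is the sample
ratio ad/bc, +∞ when bc = 0 and ad > 0.

Site-level phospho-vs-control contrasts draw control acceptors from the
same proteins as the phosphosites and match the S/T/Y composition of the
phospho set (unmatched controls are a one-line change), to avoid residue
composition acting as a confounder. No multiple-testing correction is
applied across target species; per-species raw p-values are reported.

Variant proximity uses an inclusive 10-residue distance (a variant at the
site itself is distance 0). Sites on proteins without any annotated
variant stay in denominators — absence of nearby variants is informative.
The headline enrichment compares the ≥-cutoff stratum against the
below-cutoff stratum, which are disjoint by construction.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
any particular organism's biology:

- **Phylogeny.** A fixed six-leaf ladder (reference species plus five
  relatives of increasing divergence). Per-branch substitution
  probabilities are configuration, not biology claims. The root sits
  proximal to the reference lineage: detection, model training and window
  scoring all read the reference sequences, so planted motif signal must
  survive there; pairwise reference-vs-ortholog divergence still grows
  down the ladder (defaults ≈ 0.34 … 0.89 per site). A substitution
  always changes the residue (drawn from the background excluding the
  current letter), so realized per-branch substitution fractions match the
  configured probabilities.
- **Sites.** Ancestral proteins (length uniform on [200, 800], residues
  from a Swiss-Prot-like background) receive Poisson(3) *functional* sites
  at interior acceptors (≥ flank from the termini, so windows are
  untruncated) and *neutral* true sites at ~15% of remaining acceptors.
  All true sites get a kinase motif planted by tilting the window
  background with strength 2.5 log-odds toward a randomly chosen
  same-class PSSM; only functional windows get evolutionary protection
  (substitution probability × 0.15 within ±5 of the site). A site is truly
  phosphorylated in a species when its acceptor class survives there.
- **Detection.** Each true site is detected independently per source with
  that source's sensitivity (reference species: four sources with
  sensitivities 0.55/0.50/0.45/0.20, combined ≈ 0.90, mirroring a
  multiply-covered reference; other species: one source, 0.50 → 0.30 down
  the ladder). Detected records carry true 7–25-mer peptides so remapping
  is exercised end to end. No false positives by default; an `fp_rate`
  exists for robustness experiments.
- **Variants.** Per-residue Bernoulli placement at rate 0.01, multiplied
  by the enrichment factor (default 2) within 10 residues of a conserved
  functional site; realized near/far rates are recorded in the truth
  object.
- **Alignments.** Evolution is substitution-only by default, so the truth
  alignment is the identity map and column-map oracles are exact.

What the generator does **not** emulate: indels and alignment error,
compositional heterogeneity along proteins, correlated detection between
nearby sites, kinase families beyond the four archetypes, false-positive
identifications, and isoform complexity. Passing recovery tests therefore
demonstrate correctness of the inference machinery under the stated
generative assumptions, not performance on real proteomes.

## Problem sizes and checks

The recovery suites run at sizes chosen to make their planted effects
statistically unambiguous while keeping a full run fast: 60 families
(~850 true sites) for conservation/propensity recovery; 150 families with
full window protection (~580 benchmark sites, 10 replicates) for FNR
recovery; 230 families for the variant-enrichment scaffold, thinned to
2000 sites spaced at least one full proximity window apart — spacing makes
the proximal flags independent under uniform placement, which is the
regime where the Fisher test's nominal level applies. The Fisher
implementation is checked against exact enumeration on all 270,724 tables
with total count ≤ 48.

Decile calibration of the propensity score is judged monotone when the
decile-wise true-phospho fractions deviate from their isotonic fit by no
more than twice the pooled binomial standard error and correlate with
decile rank at Spearman ρ > 0.8. A strict no-inversion rule is ill-posed:
when adjacent deciles have nearly equal true rates, inversions of order
one standard error occur with probability ≈ 1/2 at any sample size.

## Known limitations

- The FNR estimator is only defined when perfectly identical benchmark
  windows exist; under realistic divergence with partial protection the
  benchmark set can be empty (the default demo prints `n_benchmark=0`),
  and the dedicated protected scenario is used instead.
- Representative-isoform handling is a simplification: one protein per
  species per group (longest isoform, ties by smallest id).
- The propensity model is linear in the 40 motif features; kernelized
  classifiers and learned motif banks are out of scope.
- Ambiguously mapping peptides are flagged and excluded from downstream
  analyses by default rather than probabilistically assigned.
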