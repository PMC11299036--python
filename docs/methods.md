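# Methods

This note documents the models, estimators and numerical choices behind
`paleohybrid`, and what the synthetic data do and do not establish.

## The scenario and its observables

A focal clade B is hypothesized to descend from a hybridization between the
ancestors of two superclades A and C, followed by polyploid genome doubling
and diploidization.  Three observable consequences drive the package:

* **Gene-set triad.** After diploidization, each single-copy locus retains
  the copy inherited from one parent (gene trees place B with A or with C),
  except for loci where both parental alleles were homogenized (e.g. by
  gene conversion between the duplicated copies), which place B sister to
  A and C together.  Under hybridization two of the three topology classes
  are similarly frequent and one is clearly rarest; under ILS one topology
  dominates and the two alternatives are nearly equal.
* **γ, the inheritance probability.** At the reticulation each gene lineage
  traces back through the A-side parent with probability γ.  γ is estimable
  from site-pattern invariants and from rooted-triplet frequencies.
* **Split-time concordance.** Dating the B-with-A gene set gives the
  parental split t_k and the hybrid divergence t_h1; the B-with-C set gives
  t_i and t_h2.  Hybridization predicts t_i ≈ t_k and t_h1 ≈ t_h2 (both at
  the hybridization time); ILS inflates the conflicting gene set's splits
  by the coalescent sojourn, which under ILS-compatible population sizes is
  a detectable fraction of the node ages.
* **Ks peaks.** Between-species Ks distributions show the parental
  divergence peak (older) plus, only in comparisons involving B, a younger
  peak at the hybridization divergence.

## Simulator

Gene trees are drawn under the multispecies coalescent (MSC) on a species
network with one reticulation.  Node heights are in coalescent units (CU);
within each species-tree branch, k lineages coalesce at rate k(k−1)/2.
Hybrid-clade lineages reaching the reticulation height choose the A-side
stem with probability γ, independently per locus (the chosen side is
recorded as truth).  Three locus-generation modes exist:

* `network` — pure γ routing; the generative model of the γ estimators.
* `classes` / `classes_multinomial` — the locus-class mixture
  (B-with-A, B-with-C, both-retained) applied by exact largest-remainder
  quota (deterministic fixtures) or multinomially.  Both-retained loci are
  produced by coalescing the hybrid clade to a single stem lineage and
  grafting it onto the gene-tree edge above the MRCA of the parental
  superclades at max(parental split, MRCA height) plus an Exp(1) waiting
  time (truncated below the next-older node); this realizes the
  sister-to-both topology exactly while keeping coalescent-shaped heights.
  Modeling both-retained loci as a topology class (rather than simulating
  tract-level gene conversion) is a deliberate simplification: conversion
  mosaics are not tree-like and would not be recoverable by any tree-based
  classifier.

The two modes isolate the two faces of the scenario: `network` data carry
the γ signal that site patterns measure; `classes` data carry the gene-set
partition and dating signal.  Real data produced by hybridization followed
by differential copy loss combine both.  The recorded truth includes the
intended class, the realized topology class (computed from the coalescent
history by code independent of the downstream classifier), and all routing
choices.

Sequences evolve site-independently under JC69 or HKY85 along the gene
tree after converting CU branch lengths with a single clock rate.  Default
scenario: splits at 370 (outgroup), 304 (earliest-diverging ingroup
lineage), 268 (parental superclades), 248 Ma (hybridization); within-clade
crowns at 150/150/50 Ma; γ = 0.4511; class proportions
0.2334/0.3919/0.3746 — the partition 81/136/130 at 347 loci.

Two free parameters have no external estimate and were fixed by internal
consistency: the coalescent scale (0.125 CU/My, i.e. the 20 My window
between parental split and hybridization spans 2.5 CU, giving ≈ 2.7%
topology leakage per class — enough ILS to be realistic, little enough
that the class mixture survives into topology counts) and the clock rate
(0.002 subst/site/My, placing the root-to-tip depth at 0.74 subst/site so
that even outgroup comparisons stay clearly below the Jukes–Cantor
saturation boundary p = 0.75).  Both are recorded in `truth.json`.

Paralog pairs for the Ks stage use codons with a fixed second position
(families Ala/Pro/Thr/Ser), making every third-position change synonymous
and every first-position change nonsynonymous with no stop risk.  The
number of changed sites is matched to the drawn Ks by quantile rounding,
so each pair's realized NG86 estimate sits on its drawn value to ~1/L;
this isolates mixture-fitting behavior from binomial site-sampling noise,
which at Ks ≈ 3 would otherwise censor a material fraction of pairs past
the saturation boundary.  Contaminant pairs (redundant transcripts) get
uniform Ks in [0.02, 0.30], hence nucleotide identity in ≈ [0.90, 0.99] —
above the 0.90 cutoff by construction.  Codon indels are not simulated.

## Estimators

**Classifier.** Trees are pruned to A∪B∪C; B must be monophyletic; the
taxon content of B's sister decides the class.  Support semantics are left
to the caller (threshold default 0).  `bootstrap_classify` builds an
outgroup-rooted NJ tree from the alignment and scores the *position* by
the fraction of column-resampling bootstrap replicates agreeing with it;
positions below 0.70 are unresolved.  Loci whose discriminating branch is
a short coalescent waiting time are intrinsically unresolvable from
sequence data — the support filter removes them the way real analyses keep
only well-supported positions, at the cost of a ~15–20% unresolved rate.

**NG86.** Synonymous site fractions per codon count the synonymous share of
the three single-nucleotide changes per position, excluding changes to stop
codons; multi-hit codons average difference counts over all minimal
mutational pathways that avoid stops (equal weights; if every pathway is
blocked, all pathways are counted).  ps ≥ 0.75 flags saturation and the
Jukes–Cantor correction −¾ln(1 − 4p/3) is reported as infinite.

**Ks peaks.** Gaussian mixtures over a window (default [0.05, 5.0]) fit by
EM (scikit-learn, k-means++ initialization, 50 restarts), model order
chosen by BIC over k ∈ {1, 2, 3}.  Component standard deviations are
floored at 0.03 (via the covariance regularizer): per-pair Ks estimates
are effectively gridded at 1/L, and without the floor EM can collapse a
component onto one repeated value.  Peaks are labelled Ks1
(older) and Ks2 (younger) by descending mean.  Calibration rescales
distributions so the kernel-density mode (Silverman bandwidth, 512-point
grid) of a reference pair maps to a known value.

**Site-pattern γ.** With quartet roles (outgroup, P1, H, P2) and the three
bipartition classes AABB (H with P2), ABBA (P1 with H), ABAB (P1 with P2),
the hybrid-speciation invariants give γ̂ = (ABBA − ABAB) / (ABBA + AABB −
2·ABAB), clamped to [0, 1] — the symmetric form of q/(1+q) with
q = (ABBA−ABAB)/(AABB−ABAB), so swapping the parental roles maps
γ̂ → 1 − γ̂ exactly.  The Z-score contrasts ABBA with ABAB (equal under the
γ = 0 null) using the multinomial variance; p is one-sided, and a
significant call additionally requires γ̂ strictly inside (0, 1).  Columns
with gaps, ambiguity, or a polymorphic outgroup are skipped; with several
individuals per role, tallies are averaged over all role-respecting
quartets.  The bootstrap resamples individuals within ingroup roles.

**Triplet network fit.** The counts (n_AB, n_BC, n_AC) are multinomial with
the closed-form MSC probabilities given in the README.  Because three
counts carry two degrees of freedom, the two internal branches are
constrained equal by default (they span the same
parental-split-to-hybridization interval; equal ancestral population sizes
make them one quantity), leaving a just-identified (γ, t) model maximized
by L-BFGS-B from a 15-point start grid.  The input is canonically oriented
(swap A/C when n_BC > n_AB, mapping γ → 1 − γ back) so the orientation
symmetry holds to float exactness.  A γ-profile spread below 1e−6·n flags
non-identifiability (e.g. symmetric counts).  The unconstrained
three-parameter variant remains available and sits on a likelihood ridge.

**D-statistic.** D = (ABBA − BABA)/(ABBA + BABA) with ABBA = derived allele
shared by H and P2, BABA = by P1 and P2, outgroup-polarized; Z from a
delete-one block jackknife over contiguous 500-site blocks (exposed).

**Dating.** Node depths are mean path lengths to descendant tips; the
clock rate is the least-squares through-origin fit of depth against age
over calibrated nodes; ages are depth/rate with children clamped below
parents, so chronograms are always ultrametric.  Fossil ages are applied
as fixed node ages.  On outgroup-rooted NJ trees the root sits at the
midpoint of the outgroup edge, which distorts only the root node's depth;
the default pipeline calibration therefore anchors the ingroup crown
(304 Ma) rather than the root.  The concordance verdict uses 5% relative
tolerance by default (the motivating comparisons differ by well under 1%).

**Saturation screen.** The index is the mean per-site Shannon entropy over
the expectation under full randomization (cells i.i.d. from the observed
base composition); the critical value is the 5th percentile of the index
over 1,000 randomized alignments, replacing externally tabulated critical
values with a built-in null.

## What the synthetic tests do and do not show

Passing tests establish that each estimator recovers the quantities of its
own generating model (γ within ±0.03 by triplet fit at 10⁴ loci and ±0.05
by site patterns at 500 kb; Ks peaks within ±0.1 after the cutoff;
classifier 100% on true trees and ≥ 95% of well-supported NJ positions;
concordant split times in ≥ 90% of hybrid replicates; type-I error of the
gene-flow test ≤ 7%).  They do not establish robustness to features the
simulator omits: rate variation across sites and lineages, alignment
error, missing data, tract-level gene conversion, recombination within
loci, or population structure within species.  Absolute ages from real
data additionally depend on calibration density and clock violations that
mean-path-length dating does not model.

## Problem sizes

Default experiment sizes (10,000 loci for coalescent-level checks; 500
loci × 1,000 sites for sequence-level γ; 200 tree-like replicates for the
false-positive rate; 2,000 codon pairs for Ks; 50 dating replicates at 90
loci × 2,000 sites) were chosen so the full suite and the reproduction
script each complete in minutes on one core while leaving Monte-Carlo
standard errors well inside the asserted tolerances.
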