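# paleohybrid

Phylogenomic inference of **ancient allopolyploidization** — the origin of a
lineage by hybridization between two parental clades, followed by genome
doubling and diploidization.  The motivating pattern is an enigmatic clade
(call it B) that appears at *three* different positions in single-copy
nuclear gene trees: sister to parental superclade A, sister to parental
superclade C, or sister to both together.  `paleohybrid` implements the
full chain of evidence that discriminates this hybrid scenario from
incomplete lineage sorting (ILS):

1. **Ortholog curation** — redundant-transcript clustering (identity ≥ 0.98),
   two-pass paralog filtering (species coverage, reference-clade monophyly,
   aligned length ≥ 1,000 bp) and an entropy-based substitution-saturation
   screen with a randomization null.
2. **Gene-tree sorting** — outgroup rooting and classification of each locus
   by the focal clade's sister group, yielding the three gene sets; a
   bootstrap-supported variant classifies directly from sequence data.
3. **Ks distributions** — best-hit pairing, protein-guided codon alignment,
   Nei–Gojobori (1986) Ks/Ka with Jukes–Cantor correction, the identity > 0.90
   cutoff that removes spurious low-Ks transcript redundancy, and
   BIC-selected Gaussian-mixture peak fitting with cross-species rate
   calibration.
4. **Gene flow** — site-pattern invariant estimation of the inheritance
   probability γ (share of the hybrid genome from the A-side parent,
   HyDe-style), the ABBA–BABA D-statistic with a block jackknife, an
   individual-resampling bootstrap, and a one-reticulation triplet
   pseudo-likelihood network fit: with γ the A-side share and t the internal
   branch length in coalescent units,

       P(AB|C) = γ(1 − ⅔e^(−t)) + (1 − γ)·⅓e^(−t)
       P(BC|A) = (1 − γ)(1 − ⅔e^(−t)) + γ·⅓e^(−t)
       P(AC|B) = ⅓e^(−t)

5. **Chronology** — strict-clock, mean-path-length dating with fossil
   calibrations, and the split-time concordance diagnostic: a hybrid origin
   predicts the parental split dated from either parentally inherited gene
   set to agree (t_i ≈ t_k) and the two hybrid divergences to coincide
   (t_h1 ≈ t_h2); ILS predicts systematically older splits in the
   conflicting gene set.

Every stage is testable offline through the built-in **multispecies
coalescent simulator on a one-reticulation species network**: per-locus
lineage routing with probability γ, a "both-alleles-retained" locus class
(the sister-to-both topology), JC69/HKY85 sequence evolution, paralog pairs
with a target Ks mixture, and near-identical contaminant transcripts.

## Worked example

Simulate a 347-locus case study under the network model (γ = 0.4511, the
parental split at 268 Ma, hybridization at 248 Ma, root calibrated through
the 304 Ma ingroup-crown fossil) and run every stage:

```python
from paleohybrid.pipeline import PipelineConfig, run_full_analysis

cfg = PipelineConfig.from_dict({
    "seed": 3,
    "simulate": {"n_loci": 347, "sites_per_locus": 1000, "mode": "network"},
    "ks": {"n_pairs": 300, "contamination_fraction": 0.3},
    "bootstrap": {"n_reps": 50},
})
report = run_full_analysis(cfg, "demo_out")
```

The run printed (abridged from `demo_out/report.json`):

```
partition:    70 / 79 / 23 loci sister to A / to C / to both
              (175 of 347 positions below 70% bootstrap support)
hybrid_test:  gamma = 0.4817, Z = 5.63, p = 9.2e-09, significant
              bootstrap: 100% of 50 replicates significant
network_fit:  gamma = 0.4563, t_A = t_C = 0.91 coalescent units
ks:           peaks at 2.99 and 1.47 after removing 90/300 pairs
              with identity > 0.90
chronology:   t_i = 272.6, t_k = 273.8, t_h1 = 244.7, t_h2 = 244.0 Ma
              verdict: hybridization_consistent
```

Read: both γ estimators land near the generating value 0.4511 (a
347-locus draw carries binomial routing noise), the Ks mixture recovers
the generating peaks at 1.5 and 3.0 once near-identical transcripts are
cut, and the two gene sets date the parental split (generated at 268 Ma)
and the hybridization (248 Ma) concordantly — the allopolyploidy
signature.  Half the 1 kb loci are left unresolved by the 70% support
filter; longer loci resolve far more (the classifier is ≥ 95% accurate on
supported positions at 10 kb).

The same stages are available from the shell:

```bash
paleohybrid simulate --out cs --seed 4 --n-loci 60 --sites 1000
paleohybrid sort --trees cs/trees --groups cs/groups.yaml
paleohybrid netfit --counts 134 162 4
paleohybrid all --config config.yaml --out outdir
```

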