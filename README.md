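# whi3kit

Analysis toolkit for studying how a sequence-specific RNA-binding protein
mildly destabilizes its target mRNAs, modelled on the budding-yeast
Whi3/CLN3 system. Whi3 binds short GCAU/UGCAU motifs on hundreds of
mRNAs and reduces their abundance, half-life and (for *CLN3*) their
translational efficiency — each effect small (≤ 2-fold) but measurable
with the right statistics. `whi3kit` implements those statistics as a
tested, reusable pipeline for anyone analysing RIP-chip, expression
array, RNA-Seq/ribosome-profiling, qPCR shut-off or allele-ratio data of
this kind, and ships a synthetic-data generator with planted ground
truth so every stage runs, end to end, without any external download.

## What it computes

* **RIP-chip target calling** — per-gene net enrichment
  `net_g = mean_i (IP_i,g − control_i,g)` over independent experiments
  (the control is the RNA-binding-domain-deleted protein); targets are
  genes with `net_g > mean + 1.65·SD`. Gene-list overlaps are scored with
  the hypergeometric upper tail `P(X ≥ k)`, summed in log space so
  p-values far below 10⁻³⁰⁰ keep an accurate magnitude.
* **Motif statistics** — motif density (occurrences per kb, UTRs
  included), maximum count in a sliding 300-nt window, density quartiles
  (largest-remainder sizes, Q4 densest) with per-quartile mean log2
  expression response and bootstrap CIs, 3′UTR motif-presence fractions,
  binomial category enrichment, and motif-centred structure-score
  meta-profiles (±50 nt flanks).
* **Differential screen** — the three-clause mutant/over-expressor
  screen (≥ 2-fold up in mutant glucose, confirmed in a second mutant
  experiment, reversed in an over-expressor), with a per-clause audit
  table and hypergeometric target enrichment among the hits.
* **Decay kinetics** — reference-normalized shut-off courses fit by
  `ln r = −k·t + b` (free intercept, replicates pooled);
  `t½ = ln 2 / k` with analytic t-based and bootstrap CIs, and half-life
  ratios (fold stabilization) between genotypes.
* **Translational efficiency** — RPKM (genes with < 7 reads dropped),
  `TE = footprint RPKM / mRNA RPKM`, relative TE (mutant/wild-type) and
  an empirical one-tailed rank test (`p = rank / n_ranked`, genes under a
  200-read floor excluded).
* **Allele ratios** — duplex-PCR long:short band ratios from diploids
  carrying a motif-bearing and a motif-free allele; normalization
  method 1 (motif-free allele vs its partner, between genotypes; allele
  bias cancels) and method 2 (motif-bearing allele between genotypes,
  normalized to the motif-free allele), plus a seeded permutation test
  for the genotype effect.

## Worked example

```
whi3kit demo --seed 1 --out demo_out
```

generates a 200-gene synthetic study and runs every stage. Selected
lines of the printed summary (`demo_out/summary.json`):

```
"n_called": 20,                 "target_sensitivity": 1.0,
"half_life_wt": 1.893,          "half_life_mutant": 2.972,
"stabilization_fold": 1.570,    "stabilization_ci": [1.423, 1.755],
"focal_rel_te": 1.337,          "focal_te_rank": 9,
"allele_method1_fold": 1.736,   "allele_method2_fold": 1.656,
"quartile_means_motif": [-0.302, -0.083, 0.121, 0.234]
```

Reading: all 20 planted targets are recovered with no false positives;
the wild-type half-life fits at 1.89 min and the mutant at 2.97 min,
a 1.57-fold stabilization whose CI covers the planted 1.5; the focal
gene's planted 1.53-fold translational-efficiency gain is estimated at
1.34 (rank 9 of 200); both allele normalizations recover folds near the
planted 1.5; and mean expression response rises monotonically across
motif-density quartiles (it stays flat for the control motif CGUA).
Individual stages are available as `simulate`, `ripchip`, `motif`,
`screen`, `decay`, `te` and `allele` subcommands over plain TSV/FASTA
files, or directly as library functions.

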