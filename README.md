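# popdiff

Comparative population genetics for two-gene-pool diploid SNP panels — the
kind of dataset produced when two national breeding programs (e.g. Chinese
and North American soybean cultivar collections) are genotyped on a common
medium-density SNP chip.  Given genotypes, population labels and optional
QTL interval annotations, `popdiff` computes:

* **Diversity** — per-locus minor allele frequency, gene diversity
  (He = 1 − p² − q²), observed heterozygosity and polymorphism information
  content (PIC = 1 − p² − q² − 2p²q²), with per-pool and pooled summaries.
* **Linkage disequilibrium** — composite genotypic r² for within-chromosome
  SNP pairs, χ² = n·r² significance, and the distance at which binned mean
  r² decays below a threshold (default 0.1).
* **Relatedness** — Rogers genetic distance, the Loiselle marker-based
  kinship coefficient (with small-sample correction and negative-value
  truncation), and neighbor-joining trees.
* **Structure** — PCA of the (Patterson-scaled) dosage matrix, Evanno ΔK
  post-processing of model-based clustering log-likelihoods, and
  cluster-versus-origin cross-tabulation.
* **Differentiation** — Weir–Cockerham variance components a, b, c and
  θ = a/(a+b+c) per locus, ratio-of-sums multilocus and 100 kb / 10 kb
  sliding-window θ with a top-5% outlier rule, and distance-based AMOVA
  with a seeded permutation test.
* **Selection scans** — the allele-frequency-difference statistic
  t = (f₁−f₂) / √[(1/2n₁ + 1/2n₂)·f̄(1−f̄)] with log-space tail
  probabilities, population-specific-allele detection, and EigenGWAS
  (GRM eigenvector regression with genomic-control correction), combined
  into a ranked candidate table with interval-annotation overlap.

A Balding–Nichols simulator (`popdiff.simulate`) generates two-population
panels with planted divergence outliers and truth tables, so every stage is
verifiable at desk scale without external data.

## Worked example

```python
from popdiff import (SimConfig, simulate_panel, wc_fst, multilocus_fst,
                     amova, eigengwas)

cfg = SimConfig(n1=277, n2=300, n_loci=5000, background_F=0.1933,
                n_selected=0, inbreeding=0.95, admixed_fraction=0.0, seed=1)
panel, truth = simulate_panel(cfg)

fst = wc_fst(panel, ["CN", "US"])
print(f"multilocus theta = {multilocus_fst(fst):.4f}")
res = amova(panel, ["CN", "US"], n_permutations=199, seed=1)
print(f"AMOVA among-population % = {res.percent_among:.2f} (P = {res.p_value:.3f})")
```

prints

```
multilocus theta = 0.1923
AMOVA among-population % = 19.63 (P = 0.005)
```

i.e. the multilocus Weir–Cockerham estimate recovers the generating
divergence F = 0.1933 within Monte-Carlo error, and the AMOVA attributes
~19.6% of total molecular variance to the between-pool level (significant
at the permutation resolution).

The same analysis runs end-to-end from the shell:

```sh
popdiff simulate --out fixture --seed 1
popdiff run --genotypes fixture/panel.vcf --populations fixture/populations.tsv \
            --out reports
```

which writes one TSV per stage (diversity summary, LD decay profiles,
distance/kinship matrices, newick tree, PCA coordinates, per-locus and
windowed FST, AMOVA table, selection-scan candidate table) plus a JSON run
log of versions, thresholds and seeds.

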