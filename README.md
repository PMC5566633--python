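# silkshift

Comparative analysis of gene-expression evolution across spider silk-gland
types, rebuilt as a tested, reusable pipeline and exercised end-to-end on
synthetic data that emulates the study design (3 species with topology
`((Lg,Lh),Sg)`, 7 silk-gland tissues plus 3 non-silk tissues, ~2 replicates
per tissue, multi-paralog gene families).

## What it does

- **normalize** — TMM scaling factors, CPM, effective-length FPKM,
  <1-CPM filtering, per-(species, tissue) mean-FPKM profiles.
- **de** — negative-binomial exact tests (conditional on totals after
  library-size equalization): common and transcript-wise dispersion by
  conditional maximum likelihood, pooled silk vs non-silk OEST calling at
  FDR < 0.05, per-gland contrasts with fixed dispersion 0.4 when a gland
  lacks replicates, 2-fold silk flags.
- **cluster** — 1 − Spearman's rho hierarchical clustering, cut into
  (n glands + 1) groups with >50% majority-gland assignment, feature
  bootstrap clade support, centered PCA, per-tissue expression shares.
- **families** — gene-family (homology cluster) handling: 3-species
  filtering, species-specific per-tissue family sums, OEST sharing classes,
  tree-analysis eligibility.
- **phyloexpr** — the evolutionary core: Newick/NHX gene trees with
  duplication flags, species-overlap event labeling, outgroup subdivision,
  maximum-likelihood ancestral expression states under Brownian motion
  (verified against an explicit GLS oracle), node state classification
  (2-fold silk, >50% single-gland majority, else "multiple"), branch
  transition tallies, duplication-vs-speciation Fisher exact tests with
  Bonferroni correction, and the Fritz–Purvis D-statistic with permutation
  and Brownian nulls.
- **synthetic_data** — first-class simulator: birth–death gene trees along
  the species tree, Brownian expression evolution on log(FPKM+1) with
  planted gland-specific shifts, negative-binomial counts, and ground-truth
  labels for every downstream stage.

## Command line

```sh
silkshift simulate  --config cfg.yaml --seed 7 --out data/
silkshift normalize --counts data/counts.tsv --lengths data/effective_lengths.tsv \
                    --samples data/samples.tsv --species Lg --out norm/
silkshift de        --counts data/counts.tsv --lengths data/effective_lengths.tsv \
                    --samples data/samples.tsv --species Lg \
                    --contrast silk-vs-nonsilk --out de.tsv
silkshift families  --families data/families.tsv --profiles profiles.tsv --out fam/
silkshift cluster   --profiles tissue_shares.tsv --k 3 --out cl/
silkshift phylo     --trees data/trees.nhx --profiles profiles.tsv --out phylo/
```

All inputs and outputs are plain TSV/JSON/Newick; `silkshift simulate`
writes a complete input bundle plus a `truth.json` with the planted states.

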