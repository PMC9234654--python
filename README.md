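# amphigen

Analysis pipeline linking organic micropollutant burden to the population
genetics of riverine amphipods, plus a matching synthetic-study generator.
The package covers four stages, each usable on its own:

1. **Toxicity** — equilibrium-partitioning conversion of tissue
   concentrations (ng/g wet) to freely dissolved concentrations (µg/L),
   LC50 aggregation with a target→fallback species rule, per-site summed
   toxic units, and acute (>0.01) / chronic (>0.001) classification.
2. **Diversity** — missing-data QC (individuals, then loci, at a 20%
   threshold), observed/Nei-unbiased expected heterozygosity, multilocus
   F_IS, exact hypergeometric rarefaction of allelic and private-allele
   richness, a Monte-Carlo Hardy–Weinberg exact test, Chakraborty and
   Brookfield null-allele estimators, and LD-based effective population
   size (Burrows composite disequilibrium with the standard sample-size
   bias correction and a delete-one-locus jackknife CI).
3. **Structure** — pairwise Weir–Cockerham θ (multiallelic, summed
   components), genotype-permutation significance tests, hierarchical
   AMOVA on allele-mismatch distances, and Mantel / partial Mantel tests
   against waterway-distance and pollution-difference matrices.
4. **Association** — random-intercept linear mixed models fitted by exact
   profile-score optimization, AICc all-subsets model ranking, and
   recursive path models on standardized observed variables.

The `simulate` module generates complete study bundles (GenePop genotypes,
site metadata, water/tissue chemistry, LC50 records, waterway distances,
and a ground-truth table) from a forward Wright–Fisher stepping-stone
simulation in which pollution increases downstream of treatment-plant
outfalls, per-site drift intensity is tied to pollution, and optional
within-site substructure inflates F_IS at polluted sites.

## CLI

```sh
# write a synthetic 34-site, 16-locus study bundle
amphigen simulate --seed 1 --out-dir bundle/

# single stages on a bundle directory
amphigen tu bundle/ --out-dir results/
amphigen diversity bundle/ --out-dir results/
amphigen fst bundle/ --permutations 999 --out-dir results/
amphigen mantel bundle/ --permutations 999 --out-dir results/
amphigen models bundle/ --out-dir results/

# full pipeline from a YAML config
amphigen run config.yaml
```

A config file mirrors `amphigen.pipeline.PipelineConfig`:

```yaml
genotypes: bundle/genotypes.gen
sites: bundle/sites.csv
tissue: bundle/tissue.csv
water: bundle/water.csv
compounds: bundle/compounds.csv
lc50: bundle/lc50.csv
distances: bundle/distances.csv
out_dir: results
seed: 42
permutations: 999
```

All outputs are plain CSV plus a `run_metadata.json` sidecar recording the
seed and every resolved parameter; reruns with the same config are
byte-identical.

## Input formats

- **Genotypes**: canonical GenePop (3-digit alleles by default, `000`
  missing). Population names ride on individual ids (`<site>_<number>`).
- **Tables**: comma-separated UTF-8 with header rows; schemas are
  documented in `amphigen/tables.py`.
- **Distances**: square CSV matrix, header row and index column both site
  ids.

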