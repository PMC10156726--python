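# cavepopgen

Detection and classification of **repeated evolution** across replicate
cave/surface population pairs from multi-population SNP data.

When the same species colonizes caves independently in different river
drainages, the same traits — eye loss, depigmentation, altered sleep and
metabolism — evolve again and again.  Three genetic routes can produce
that repetition at a locus: selection on **standing variation** already
segregating in the ancestral surface population, **migration** spreading
one adaptive allele between caves, and **independent de novo mutations**
in each cave.  This package implements the full inference stack for
telling those routes apart from population allele frequencies:

- **Site filters and summary statistics** — the biallelic / missingness /
  MAF / all-heterozygous filter cascade; per-site and 50-kb-windowed pi,
  Dxy and Hudson Fst (ratio-of-sums aggregation); per-gene summaries;
  frequency-based ABBA-BABA D with a block jackknife; a one-sided
  rank-sum comparison of cave vs surface genome fractions under selection.
- **Sweep intersections** — cave-adaptive genes (swept in a cave, clean
  in its lineage's surface population) and overlapping sweeps across all
  caves, consuming diploS/HIC-style 5-kb window classification tables.
- **Eigen reuse scan** — eigen decomposition of unit-normalized
  allele-frequency-change vectors in 50-SNP windows across replicate
  surface→cave pairs, with a 10,000-permutation genome-wide null:
  *allele reuse* (one shared allele moving in every cave) loads on
  eigenvector 1 with a common sign; *locus reuse* (each lineage moving
  its own allele at the same locus) splits the spectrum along lineage
  lines.
- **Convergence modes** — a composite-likelihood comparison of neutral /
  independent / standing / migration / two mixed models around each
  candidate gene (gene ± 10 kb, 50 evenly spaced proposed sites, full
  parameter grids), built on the coancestry of standardized allele
  frequencies: the rate at which *between*-population coancestry decays
  with recombination distance from the selected site is what separates
  the modes.
- **Dating** — allele split times from Dxy = 2·mu·T and admixture onset
  from ancestry-tract lengths, T_admix = 1/(L_M·p_B).
- **Downstream tests** — QTL-overlap permutation test, Fisher exact
  enrichment, Welch gene-length comparisons, Kruskal-Wallis sweep-age
  comparisons, phenotype-keyword categories, and a convergent
  TFBS-loss filter (≥80% presence in every surface population, <20% in
  every cave population).
- **Synthetic data** — a two-lineage Wright-Fisher frequency simulator
  with sweeps of known mode implanted by exact frequency surgery,
  emitting every input format (VCF, GFF3, BED, sweep/motif/GO tables)
  plus truth labels, so the whole stack is exercised end-to-end against
  known answers.

See `docs/methods.md` for the models, parameter defaults, numerical
choices, and what the synthetic experiments do and do not show.

## Worked example

Simulate a 300-kb region where a 100-kb gene carries a sweep from
standing variation (s = 0.1, standing for 500 generations) in all three
cave populations, then ask which convergence mode the composite
likelihood prefers:

```python
from cavepopgen import synthdata as sd, convergence as conv

# swept region with known truth, and a neutral panel for the coancestry F
panel, gene, truth, config = sd.make_convergence_region("standing", seed=1)
bg = sd.DemographyConfig(snp_count=8000, chrom_length=4_000_000, seed=999)
neutral, _ = sd.simulate_neutral_panel(bg, draw_haplotypes=False)
F = conv.estimate_neutral_F(neutral, thin_bp=500)

caves = tuple(p.name for p in panel.populations if p.ecotype == "cave")
specs = conv.default_model_specs(caves, ne=config.branch_ne)
res = conv.fit_gene(panel, gene, specs, F)
print("best model:", res.best_model)
print("MCLE:", res.mcle)
print("selected site:", int(res.best_site), "->", res.site_class)
for m, ll in sorted(res.model_logliks.items(), key=lambda kv: -kv[1]):
    print(f"  {m:<16s} {ll:10.1f}")
```

prints

```
best model: standing
MCLE: {'s': 0.001, 't_st': 1000.0, 'g': 0.01}
selected site: 148775 -> intron
  standing           -31634.8
  mixed_standing     -31634.8
  migration          -31636.3
  mixed_migration    -31636.3
  independent        -31668.8
  neutral            -40890.7
```

The standing model wins; every selection model beats neutral by ~9000
log-likelihood units (the sweep is unmistakable), while standing beats
migration by the small margin carried by the distance-decay of
between-cave sharing — exactly the contrast the method rests on.  The
best proposed site lands ~1.2 kb from the true selected position
(150,000) and is classified intragenic.

The same stages are available from the shell:

```bash
cavepopgen simulate --out fixture --seed 3 --snps 4000 \
    --chrom-length 2000000 --sweep migration:1000000:0.1
cavepopgen scan --vcf fixture/panel.vcf --samples fixture/samples.tsv \
    --design design.tsv --gff fixture/genes.gff3 --seed 4 --out scanout
cavepopgen run --config pipeline.yaml --seed 5
```

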