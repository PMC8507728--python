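# triomic

Analysis of paired **tumour mucosa / visually normal mucosa / stool** 16S
genus count tables from colorectal-cancer cohorts, built for studies where
every patient contributes a triplet (or a tumour+normal duplet) of
samples.  The package takes a genus × sample count table and clinical
covariates, and produces:

- **environment-preference categories** per genus — *tumour* (more
  abundant on tumour mucosa than in stool), *mucosa* (also enriched on
  visually normal mucosa vs stool), *tumour-specific* (additionally
  enriched on tumour vs normal mucosa), *stool*, and *no-difference* —
  from paired Friedman + Wilcoxon signed-rank screens on clr abundances,
  with a parallel Cochran Q / McNemar incidence screen;
- **clinical associations** per genus and sample type via rank regression
  (Jaeckel dispersion with Wilcoxon scores) and drop-in-dispersion tests,
  including a grade × location interaction model over three location
  groups (right/transverse, left, rectosigmoid/rectum);
- **co-occurrence screens** among tumour genera (Fisher exact on 2×2
  presence tables, BH-corrected);
- **tumour microbial subtypes (TMS1–TMS3)** by Ward hierarchical
  clustering of tumours on the Aitchison distance between clr-transformed
  tumour-genus subcompositions, genus co-clusters (B1–B6), and the derived
  per-tumour **oral fraction** and **microbial pathogens burden** scores;
- **alpha/beta diversity**: observed richness, Chao1, Shannon (bits),
  paired comparisons, PERMANOVA and PCoA on Aitchison distances;
- a seeded **synthetic triplet-cohort generator** (logistic-normal
  multinomial) that plants all of the above structure, so the entire
  pipeline is testable end to end without any sequencing data.

## The statistics in brief

Counts are compositional.  Per sample, zeros are multiplicatively
replaced (δ = 0.65/depth) and abundances mapped to centred log-ratio
coordinates, clr(x)ᵢ = log xᵢ − mean log x, so that Euclidean geometry is
Aitchison geometry.  Genus-level inference is rank-based: a model
y = Xβ + e is fitted by minimising the Jaeckel dispersion
D(β) = Σᵢ a(R(eᵢ)) eᵢ with Wilcoxon scores a(i) = √12·(i/(n+1) − ½), and
nested models are compared with the drop-in-dispersion statistic
F = (RD/q)/(τ̂/2) ~ F(q, n−p−1), with τ̂ from the Koul–Sievers–McKean
window estimator.  Exact r×c Fisher tests enumerate the margin-fixed
table lattice when it is small enough (≤10⁷ tables) and otherwise use
seeded margin-preserving Monte Carlo; a Pearson chi-square variant is
provided for the large clinical contingency tables.  Multiplicity is
controlled with Benjamini–Hochberg q-values at FDR < 0.1 throughout.

## Worked example

```python
from triomic.simulate import GeneratorConfig, generate
from triomic.io import filter_taxa
from triomic.compositional import clr_transform_counts
from triomic.categories import abundance_screen, assign_categories
from triomic.subtyping import subtype_cluster, oral_fraction

# a synthetic cohort: 120 patients x 3 samples, 200 genera, with planted
# environment preferences and 3 tumour subtypes
table, clinical, truth = generate(GeneratorConfig(seed=1))

filt = filter_taxa(table)             # >=9 reads in >=3 samples of a type
clr = clr_transform_counts(filt.counts)
cats = assign_categories(abundance_screen(clr, filt))
print(cats["category"].value_counts().to_string())

tumour_genera = list(cats.index[cats["tumour_flag"]])
res = subtype_cluster(filt, tumour_genera)   # TMS1..TMS3
print(res.assignments["tms"].value_counts().sort_index().to_string())

frac, kw = oral_fraction(filt, truth.genus["origin"], res.assignments)
print(frac.groupby(res.assignments["tms"]).median().round(1).to_string())
```

prints

```
category
no_difference      74
tumour_specific    42
stool              41
mucosa             39
other               4
tms
1    28
2    36
3    56
tms
1    49.2
2    41.7
3    20.6
```

The category counts recover the generator's plan (40 mucosa, 40
tumour-specific, 40 stool, 80 no-difference; a handful of rare genera near
the detection limit are misassigned).  The three subtypes match the
planted 0.26/0.31/0.43 mixture, and the per-subtype median oral fraction
is ordered TMS1 > TMS2 > TMS3 because the subtype-1 signature genera are
the oral-annotated ones (Kruskal–Wallis p ≈ 3×10⁻¹⁶).

The same stages are available as a CLI:

```bash
triomic simulate -o run/ && triomic filter -d run/ \
  && triomic categorise -d run/ && triomic subtype -d run/ \
  && triomic report -d run/
```

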