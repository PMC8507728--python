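# Methods

## Scope and data model

The package operates downstream of amplicon processing: its input is a
genus × sample table of integer read counts, sample metadata linking each
sample to a patient and an environment (tumour mucosa, visually normal
mucosa, stool), and a per-patient clinical table.  Counts are the single
source of truth; relative abundances and clr values are always derived in
memory, never stored.  Paired three-environment analyses use only
patients with complete triplets; tumour/normal analyses may also use
duplet patients.

Genera are filtered with the contamination guard used for this kind of
cohort: a genus is kept iff some sample type has at least 3 samples each
carrying at least 9 reads of it.  At the shallowest plausible depth
(2,968 reads) the 9-read threshold corresponds to a 0.3% relative
abundance detection limit.  The filter is idempotent and monotone in the
sample set; both properties are tested.

## Compositional treatment

Zeros are replaced multiplicatively: in a closed composition with z
zeros, each zero becomes δ and the non-zero parts are scaled by 1 − zδ,
preserving all ratios among observed parts.  δ is per sample, 0.65/depth
— 65% of that sample's count detection limit.  The 0.65 factor is the
common multiplicative-replacement convention; the method itself does not
fix the constant, so it is a configurable argument
(`clr_transform_counts(..., delta_fraction=...)`).

clr uses natural logs (distances are base-invariant up to a global
constant).  The Aitchison distance is the Euclidean distance between clr
vectors; perturbation invariance, scale invariance and the triangle
inequality are property-tested at 1e−9.

## Hypothesis tests

Standard tests are delegated: Wilcoxon signed-rank and Mann–Whitney to
scipy (exact enumeration when the nonzero/untied sample is small, normal
approximation with continuity correction otherwise), Kruskal–Wallis to
scipy, BH to statsmodels, PERMANOVA and PCoA to scikit-bio.  Friedman is
computed in-package with the tie-corrected chi-square statistic because
the k = 2 case is needed (scipy requires k ≥ 3); it is cross-checked
against scipy for k = 3.  Cochran's Q uses the classical column/row-sum
formula with degenerate inputs (all rows constant) returning p = 1 with a
warning.

The r×c Fisher exact test is implemented here because no installed
Python library provides one beyond 2×2.  The two-sided p-value follows
the probability-at-most-observed rule with a 1e−7 relative tolerance on
the comparison (the convention of the standard exact-test
implementations).  When the lattice of margin-fixed tables has at most
10⁷ nodes (counted by dynamic programming over column remainders) the
lattice is enumerated — rows recursively, the penultimate row vectorised,
the last row implied; otherwise the test switches to seeded
margin-preserving Monte Carlo (sequential hypergeometric row sampling,
p = (1 + #extreme)/(1 + reps)).  The enumeration path agrees with the
closed-form hypergeometric sum on 2×2 tables to 1e−12 and with R's
`fisher.test` on published 2×3 and 3×3 clinical tables at 6 decimals.

A Pearson chi-square wrapper (no continuity correction) is provided for
large clinical contingency tables; subtype–clinical tests accept
`categorical_test="fisher"` or `"chi2"`.  The two can differ visibly
(e.g. 0.763 vs 0.729 on a 2×3 gender table); which one a given report
used is worth checking before comparing numbers.

## Rank regression and the drop-in-dispersion test

Slopes minimise the Jaeckel dispersion D(β) = Σ a(R(eᵢ))eᵢ with Wilcoxon
scores; ties in residual ranks get average ranks, extended linearly into
the score function.  D is convex and piecewise linear; it is minimised
with Nelder–Mead from the least-squares start plus three seeded jittered
restarts (guarding against flat facets), convergence tolerance 1e−8 on D.
On small problems the fitted slope lands on the grid-search minimising
facet of D to 1e−3.  The intercept is not identified by D and is taken as
the median of the slope-fit residuals.

The scale τ is estimated in the Koul–Sievers–McKean fashion: a
uniform-kernel density estimate at zero of the pairwise residual
differences, bandwidth c·σ̂·n^(−1/5) with c = 1 (configurable) and σ̂ the
MAD-based residual scale, then 1/(√12·f̂(0)) with the
√(n/(n−p−1)) degrees-of-freedom correction.  Nested models are compared
with F = (RD/q)/(τ̂/2) against F(q, n−p−1).  Calibration is demonstrated
empirically: under the null the drop-test p-values are uniform (KS test
over 500 replicates), with rejection rates slightly conservative at the
5% level; under t₃ noise at n = 200 the slope estimate is unbiased to
±0.05.

## Screens and category rules

Abundance screening runs per genus on clr values over triplet patients: a
Friedman test across the three environments gates (at BH q < 0.1 across
genera) three paired Wilcoxon post-hocs — tumour vs stool, normal vs
stool, tumour vs normal — each BH-corrected across the gated genera, with
direction from the sign of the median paired difference.  Gating keeps
the post-hoc family conditional on an overall difference; whether to gate
was an open design choice, resolved in favour of gating because it
mirrors the stated test order and controls the pairwise family.

The flag pattern maps to categories: tumour ⇔ tumour-vs-stool up; mucosa
⇔ tumour AND normal-vs-stool up; tumour-specific ⇔ tumour AND
tumour-vs-normal up (taking precedence over mucosa when both hold, as the
more specific label); stool ⇔ stool above both mucosal environments;
no-difference ⇔ no significant pairwise difference; everything else is
reported as *other* rather than silently dropped.  The mapping is a pure
function of the flags and is exhaustively property-tested.

Incidence screening mirrors this with Cochran Q and McNemar post-hocs on
presence/absence, and reports mucosa-only genera (detected on mucosa,
never in stool).

Clinical associations test only genera present in ≥ 10 samples of some
clinical group.  Grade is coded ordinally (1–3) for "increasing grade"
models and as a factor inside the interaction model; in-situ/ungraded
tumours are excluded from grade models.  The interaction analysis
compares clr ~ grade + location + grade:location against the additive
model by drop-in-dispersion; interaction columns whose sparse cells make
them collinear with the main effects are dropped.  Per-cell effects for
interaction-significant genera add a single cell-deviation indicator to
the additive model: its coefficient sign gives the direction and its
drop-in-dispersion test the cell p-value.  The exact contrast convention
behind published per-cell claims is not recoverable from a methods
section alone; this one is explicit and reproducible.  BH families are
per (sample type × model), mirroring per-column reporting of such tables.

## Subtyping

Tumour samples are re-closed over the tumour-genus list (subcomposition),
zero-replaced and clr-transformed; tumours are clustered on Aitchison
distance and genera on Euclidean distance between clr rows, both with
Ward linkage (complete/average configurable — the linkage behind the
published trees is unstated, and Ward is the standard choice for this
geometry).  Trees are cut at fixed k (3 subtypes, 6 genus groups) because
the subtype system being emulated has exactly that shape; each subtype is
re-cut in two for the a/b subgroups.  Clustering is deterministic; labels
are canonicalised — TMS1 is the subtype with the highest median pathogen
burden when a panel is supplied, otherwise the smallest subtype first,
with lexicographic tie-breaks — so labels are stable across sample
orderings and reruns.  Computing clr on the subcomposition (rather than
the full composition) was the open choice taken; the full-composition
route is available by passing the full genus list.

The oral fraction is the summed relative abundance of oral-annotated
genera per tumour (annotation is an input; genera missing from it count
as "unknown").  The pathogen burden is the per-tumour count of detected
panel genera; the default panel is the set flagged by the clinical
associations as up in high grade or advanced pT at q < 0.1, and a
user-supplied panel is accepted.

## Diversity

Alpha diversity (observed genera, bias-corrected Chao1, Shannon in bits,
base configurable) is computed on unfiltered counts — the taxa filter
would bias richness — and compared between environments with paired
signed-rank tests, BH across the nine metric × pair tests.  Ordination
is PCoA on Aitchison distances, which equals PCA of the clr matrix up to
sign (cross-checked at 1e−6); a deterministic ordination was preferred
over stress-minimising NMDS, affecting plots only.

## The synthetic cohort generator

The generator is the package's study-design stand-in: logistic-normal
multinomial counts with planted structure, so effects live directly in
clr space where the analysis operates (a Dirichlet-multinomial would not
give that control).  Per patient: a subtype from the 0.26/0.31/0.43
mixture; per sample: genus log-abundances = baseline (N(0, 1.25²), a
realistic 2–3 decades of abundance after genus-level aggregation and
filtering) + environment shift + subtype signature shift (tumour samples
only, +2 clr on 10 signature genera per subtype) + patient effect
(N(0, 0.5²), shared across the triplet) + noise (N(0, 1)); proportions by
softmax; counts multinomial at a log-normal depth (median 20,000,
clipped to [3,000, 240,000], the depth range such cohorts report).

Environment effects (default Δ = 2 clr): planted symmetrically, half up
in preferred environments and half down elsewhere — mucosa (+1, +1, −1)
over (tumour, normal, stool), tumour-specific (+1, −1, −1) — with the
stool-category genera absorbing the balancing counter-shift that makes
the mean planted shift equal in every environment (default (−2, 0, +2)).
Two artefacts are avoided by construction.  Without mean balance, clr
closure smears a ~0.4-clr artefactual shift over every unplanted genus.
Without the symmetric split, one environment becomes much more
concentrated (log-sum-exp of shifts), rare genera fall below the
detection limit there specifically, and zero replacement converts that
censoring into spurious paired differences.  Both artefacts are real
phenomena of compositional pipelines; the default design avoids them so
that planted labels are recoverable, and either can be re-introduced by
configuring asymmetric plans.

A plain "tumour" category (up vs stool, but neither tumour-vs-normal nor
normal-vs-stool significant) has no cleanly plantable effect pattern: at
120 paired samples any intermediate normal-mucosa level is itself
significant, which relabels the genus mucosa or tumour-specific.  The
plan slot exists (planted with a half-effect normal shift) but defaults
to zero; the default plan is 40 mucosa, 40 tumour-specific, 40 stool,
80 no-difference out of 200 genera.

Subtype signatures are drawn from the tumour-specific pool (extra
tumour-only abundance on a mucosa genus would flip its
tumour-vs-normal flag for a third of patients).  Subtype shifts are
zero-sum per tumour sample: each subtype lifts its own signature genera
and depletes the next subtype's by the same amount — real microbial
subtypes are defined by absence patterns as much as presence, and a
one-sided lift would add a small clr closure offset to every tumour
sample that leaks into the paired environment screens.  Their oral/gut
origin is
laid out so subtype 1's signatures are oral, subtype 2's mixed and
subtype 3's gut, planting an ordered oral fraction.  Grade and location
are drawn from subtype-conditional tables calibrated to the published
subtype-conditional frequencies (subtype 1 right-sided and high-grade);
all other covariates come from cohort-like marginals independent of
subtype.  Optional knobs plant per-grade clr slopes and a single
grade × location cell effect on no-difference genera for exercising the
association models.

What the generator does *not* emulate: phylogenetic structure (so no
UniFrac), overdispersion beyond the logistic-normal noise, batch or
extraction effects, contamination, and genus-genus ecological
interactions beyond the planted signatures.  Passing recovery tests on
this design shows the pipeline correctly inverts its own generative
assumptions — not that real cohorts are this clean.

## Problem sizes and numerics

Recovery and calibration figures use the design the tests state: 120
triplets × 200 genera for category recovery and subtype ARI (5 seeds);
n = 200, 200 replicates for slope bias; n = 50, 500 replicates for null
calibration; enumeration oracles at n ≤ 15 where the exact null is
computed by dynamic programming rather than brute force.  Chi-square
approximations (Friedman, Cochran Q) are compared to exact permutation
nulls in the decision-relevant tail; near p = 1 the permutation null is
coarsely discrete and the approximations undershoot it — a property of
the approximations, not of this implementation.  Monte-Carlo paths
(Fisher r×c, PERMANOVA) are seeded and reproducible; all cohort
generation flows from one seed through per-component child streams, so
components can be regenerated independently.

## Known limitations

- The Fisher Monte-Carlo p is a simulation estimate; at 200,000 draws its
  standard error near p = 0.002 is ~1e−4.  Raise `mc_reps` for sharper
  tails.
- τ̂ uses a single fixed-constant bandwidth; heavy ties or tiny samples
  (n − p ≤ 5) deserve scepticism, as with any window estimator.
- The a/b subtype subgroups re-cut each subtype in two unconditionally;
  no claim is made that two subgroups are the "right" number.
- Alpha diversity is not rarefied; with depths spanning two orders of
  magnitude, richness comparisons lean on the paired design to absorb
  depth effects rather than on rarefaction.
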