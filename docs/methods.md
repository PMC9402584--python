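# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot demonstrate.

## Fin geometry

An outline is an ordered simple polygon; the implicit closing edge joins
the last vertex to the first. Area is computed by the shoelace formula,
the perimeter as the polyline length, convex area from the hull of the
vertices, and the major axis as that of the ellipse with the same second
central moments as the filled polygon (the standard image-analysis
definition; polygon moments are computed by Green's-theorem formulas, so
no rasterization is involved). Height and width are the bounding-box
extents along the image y (dorsoventral) and x (anteroposterior) axes.
Outlines must therefore be pre-oriented — anterior left, dorsal up —
exactly as digitized lateral-view reconstructions are. Consequences:

- `circ`, `round`, `sol` are invariant to rotation; `he_wi` and `ar`
  deliberately are not (they reference the anatomical axes).
- All five are invariant to translation and scale, so specimens
  digitized at different magnifications are comparable.

Binary masks are traced through pixel corners (the unit squares of the
foreground component are dissolved and the exterior ring taken), so a
filled k×k square yields area exactly k². This makes the analytic tests
exact instead of convention-dependent. Masks must contain exactly one
foreground component, and a component touching all four borders is
rejected as a segmentation failure.

Length conversions (standard/fork → total) are species-specific affine
maps `total = slope·measured + intercept` with `slope > 0`; non-positive
results raise rather than propagate.

## PGLS speed model

The response is speed in BL/s, untransformed (a `log10_response` switch
exists; predictions are always returned on the BL/s scale). The residual
covariance is pure Brownian motion on the dated tree: `C[i,j]` is the
root-to-MRCA shared path length in Myr, and a root (stem) edge present in
the Newick counts into every entry. No Pagel's λ or OU transformation is
applied. Estimation is maximum likelihood throughout — GLS coefficients,
`σ̂² = r̂'C⁻¹r̂/n` — so AIC (`2k − 2logL`, `k` = coefficients + 1) is
comparable across candidate designs. `R² = 1 − r̂'C⁻¹r̂ / r̂₀'C⁻¹r̂₀`
against the GLS intercept-only model.

Species with several records become randomly resolved polytomies with
zero-length internal branches; terminal branches get an ε-jitter of
`1e-6 ×` tree depth so `C` stays positive definite. The fitted model thus
treats same-species records as (nearly) perfectly correlated, which has
two knock-on effects worth knowing about:

- any true independent within-record noise inflates `σ̂²` by roughly
  `noise²/ε` — the model has no place else to put it;
- contrasts between same-species records (which differ in length, mode,
  condition) are weighted very heavily, so record-level coefficients can
  be estimated extremely precisely when the model is exactly true.

Categorical terms are dummy coded with the alphabetically first level as
reference (burst, free, anguilliform, chondrichthyan). The `Group` term
is clade membership (chondrichthyan/osteichthyan). Collinearity uses the
Fox–Monette generalized VIF from correlation-matrix determinants;
leave-one-out cross-validation drops one record at a time (pruning a tip
is equivalent to taking the covariance submatrix) and reports the squared
Pearson correlation of observed vs fixed-effects predictions. Predictions
for new observations use the fixed effects only — no phylogenetic BLUP —
because fossil taxa are not tips of the extant tree. `prediction_se`
propagates coefficient sampling error (`σ̂²(X'C⁻¹X)⁻¹`) into any
prediction; it excludes the BM residual variance of a hypothetical new
tip.

## Supertree pool

MRP characters follow Baum–Ragan coding: one binary character per
non-trivial clade per source tree; taxa absent from a source are missing
(`?`). Parsimony lengths are Fitch counts with `?` as the full state set;
polytomies are resolved arbitrarily before scoring (any resolution
upper-bounds the polytomy score; all trees produced by the search are
binary). The heuristic search uses random-addition starts followed by
first-improvement hill climbing over NNI (default) or SPR
neighbourhoods; equally parsimonious trees are collected across starts,
deduplicated by their unrooted bipartition sets, and topped up by
sampling with replacement (logged) when fewer distinct optima exist than
requested. An exhaustive enumerator (each unrooted topology exactly once,
up to 8 taxa) serves as the optimality oracle in tests.

Time calibration is deliberately basic: tip age ~ Uniform(youngest,
oldest) within the taxon's stratigraphic interval; each node's age is the
oldest of its children's ages and any applicable minimum-age constraint,
plus a minimum branch length (default 1 Myr). Every branch is therefore
at least `min_branch` long and parents are strictly older than children.
Constraints attach to the MRCA of their taxon set only when that set is
monophyletic in the topology at hand; otherwise they are skipped with a
warning — under supertree uncertainty some true clades legitimately fail
to be recovered. A small table of ICS (2022) chronostratigraphic unit
boundaries ships with the package for convenience
(`tree_assembly.CHRONOSTRAT_UNITS`); a unit-derived constraint defaults
to the unit's youngest bound, the conservative minimum.

## Ancestral reconstruction

Under BM, the joint ML estimates of all internal states minimize
`Σ_edges (x_child − x_parent)²/length`. That is a linear solve against
the grounded graph Laplacian of the tree (edge weights 1/length, tips
clamped at their data), and its solution at each node equals the GLS mean
of the tips on the tree re-rooted at that node. Per-node variances are
`σ̂²·diag(L⁻¹)` with `σ̂²` the ML rate from the root-level GLS fit; they
are reported but not consumed downstream, except where noted below.
Estimates are convex combinations of tip values (so the root always lies
within the tip range) and equivariant under adding a constant.

Ancestral *shapes* apply the same solve to all 204 landmark coordinates
at once (one factorization per tree). No semilandmark sliding is
performed: the landmarks are equal-arc-length interpolations, and
sliding would change what the type III points mean; GPA removes
translation, scale and rotation only, with reflections forbidden
(rotation determinant +1). The GPA consensus is initialized from the
normalized mean shape, which makes the procedure idempotent on aligned
input (a fixed point to ~1e-9 at the default tolerance 1e-10). Mean
ancestral shapes are coordinate-wise means of aligned configurations.
Reconstructed shape polygons can self-intersect slightly; the metrics
are still computed on the polygon as given, with a warning.

Size normalization re-predicts every taxon at a common total length
(default 0.1 m = 10 cm on the model's scale), leaving other predictors
unchanged; taxa differing only in length collapse to identical
normalized speeds.

For recovery checks, the pooled uncertainty of a root estimate combines
three components: the between-tree spread of per-tree estimates, the
mean within-tree reconstruction variance, and (end to end) the sampling
error of the fitted regression coefficients, which shifts all tip
predictions coherently and is invisible to the first two components.
Density plots of per-tree point estimates alone (the usual presentation)
understate the total uncertainty accordingly.

## Trend models

BM (`k = 2`) and drift (`k = 3`) fits are closed-form GLS under the same
`σ²C` covariance; the drift design is `[1, T]` with `T` the root-to-tip
depths. On an ultrametric tree `T` is constant and the model is rejected
(`IdentifiabilityError`, depth variance `< 1e-10·mean²`). `ΔAIC =
AIC_BM − AIC_drift`, negative favouring BM; nesting guarantees
`ΔAIC ≥ −2`. Degenerate (constant) traits floor `σ̂²` at 1e-12 with a
warning instead of producing an infinite likelihood. Trees where either
fit fails are excluded from pool summaries with a log message. Both the
raw and the size-normalized speed datasets are run identically.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the empirical study: 160
records over 61 extant species (body lengths 4–105 cm, log-uniform;
burst/cruising and free/non-free categoricals; one fin per species built
from the parametric two-lobe outline family), an ultrametric extant tree
(pure-birth, depth 100 Myr), 41 fossil taxa on a birth–death tree whose
extinct tips are the fossils (root placed at 520 Ma, 150 Myr span), 37
partially overlapping source topologies induced from the true tree, and
stratigraphic ranges of a few Myr around the true tip ages.

Speeds are generated from `Speed ~ Length + Mode + HeWiCF + Cond` with
coefficients (5.0, −0.02 per cm, −1.5 for cruising, +0.5 per he_wi unit,
−0.4 for non-free), a BM residual of rate 0.002 (BL/s)²/Myr simulated on
the *record* tree (polytomies resolved exactly as the fitting step
assumes), and — by default — no additional iid noise: the generator's
default conditions are the fitted model's own assumptions, under which
`σ̂²` is consistent and standard errors mean what they say. A
`noise_scale` dial exists specifically to probe what happens when that
assumption is broken (briefly: `σ̂²` absorbs `noise²/ε` and becomes
uninterpretable, while coefficient estimates stay unbiased).

Fossil fin shapes evolve by BM directly on the generating parameters —
height-to-width ratio (root 1.2, rate 6e-4/Myr), chord, dorsal-share
asymmetry, log maximum body length — so the measured `he_wi` of a tip
outline *is* the BM variable by construction, and true ancestral metric
values exist at every node. An optional drift on `he_wi` (scaled by the
generating speed coefficient) produces a known trend in derived speeds;
the default drift is zero, matching a no-trend null.

What the generator does **not** emulate: photographic segmentation error
and digitization noise; fin-shape allometry and ecology-correlated
predictor structure; missing or asymmetric stratigraphic knowledge
(ranges always contain the true age); source-topology conflict beyond
taxon subsampling (sources are always compatible with one true tree);
and any form of trait-dependent diversification. Passing tests therefore
demonstrate the correctness and calibration of the inference machinery
under its stated model — not robustness of the scientific conclusions to
violations of that model in real data.

## Problem sizes and numerical settings

Tests and the acceptance script run the fossil pipeline with 6–8 MRP
topologies × 10–12 calibrations (pools of 60–96 trees) and shape-route
subsamples of ~12 trees; the pipeline accepts the full-scale settings
(45 × 100, subsample 1000) through its configuration. Other notable
constants: GPA tolerance 1e-10 / 200 iterations; polytomy ε-jitter
1e-6 × tree depth; minimum calibration branch 1 Myr; σ² floor 1e-12;
GVIF flag threshold 2; Nelder–Mead oracles in tests run to ~1e-13
tolerances so 1e-6 agreement checks are meaningful.

## Known limitations

- MRP search is heuristic; on large, conflict-rich matrices the
  requested number of distinct optimal topologies may not exist, in
  which case the pool repeats topologies (logged).
- The drift model estimates a single linear trend; rate shifts,
  early-burst or OU dynamics are out of scope.
- LOO cross-validation refits per record with the full candidate design;
  it does not re-run model selection inside the loop, so its R² is
  conditional on the chosen formula.
- Shape-route summaries are keyed explicitly by clade name (plus the
  root) rather than reported positionally, so a reader never has to
  infer which value belongs to which node; published positional lists of
  clade means are ambiguous in exactly that way.
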