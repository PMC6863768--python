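# Methods

## Phenotype model and binarization

The raw phenotype is the diameter (mm) of the cleared predation zone a
predator produces on a lawn of one prey organism. Zones are non-negative;
a missing assay is a missing value, and the affected strain is simply
excluded from that prey's ranking (it receives no label and enters no
contingency table).

Per prey, the n scored strains are ranked and split into tertiles with
group size k = ⌊f·n⌋, f = 1/3 by default: the k largest zones are
*superior*, the k smallest *inferior*, the rest *moderate*. The fraction f
is a parameter (0 < f ≤ 1/2) because widening the moderate band trades
statistical power for a cleaner superior/inferior contrast.

Ties at a group boundary are ambiguous under any rank-based rule. The
default (`demote`) moves the whole tied block to moderate, which never
fabricates a distinction between strains with equal phenotypes but can
shrink or even empty a group (all-equal columns become all-moderate). The
alternative (`expand`) enlarges the group to include every strain tied with
the boundary; a strain qualifying for both groups under heavy ties becomes
moderate. Continuous phenotypes make boundary ties a measure-zero event,
but deterministic (noise-free) synthetic data hits them systematically —
there `expand` is the only rule that leaves both tertiles populated, since
all non-carriers share the baseline value exactly.

*Predatory breadth* is the count of prey (out of the panel) for which a
strain is labelled superior; it is reported as a ranking table.

## Association screen

For cluster g and prey p, the 2×2 table counts carriers/non-carriers among
superior (a, c) and inferior (b, d) strains. The test is the two-sided
Fisher exact test: the total hypergeometric probability, at fixed margins,
of every table no more probable than the observed one. The implementation
delegates to `scipy.stats.fisher_exact`; the test suite verifies it against
an independent exact-rational enumeration oracle (integer weight
comparisons, no floating point until the final division) over all tables
with both margins ≤ 12, at 1e-9.

A record passes when the association is positive (carriage rate higher
among superior strains), p < 0.05, sensitivity 100·a/(a+c) ≥ 70 and
specificity 100·d/(b+d) ≥ 80. The three cutoffs are conjunctive, matching
Scoary's screening semantics. The raw Fisher p is the screening statistic;
Benjamini–Hochberg values (adjusted within prey, via
`statsmodels.stats.multitest`) are reported in the output for transparency
because the screen is deliberately low-stringency — with ~600 informative
clusters and 10 prey, some raw-p hits are expected by chance, and the BH
column lets a reader judge each hit's FDR standing. Negative associations
are recorded but can never pass: the screen seeks genes whose *presence*
marks superior predators. Clusters uniform (all present / all absent)
across a prey's informative strains carry no signal and are skipped for
that prey; a prey without both superior and inferior strains is skipped
with a warning.

Note a granularity constraint: with tertiles of size k the smallest
achievable two-sided p is 2/C(2k,k), so k = 3 (9-strain subsets) cannot
reach p < 0.05 with any imperfect table, and even k = 4 admits only
near-perfect separations. This matters for the saturation analysis below.

## COG profile comparison

Hits are mapped to COG functional-category letters (multi-letter
assignments contribute one count per letter; unassigned clusters are
excluded). Observed counts are compared with expected counts from the
background letter frequencies of the parent genomes by a χ² goodness-of-fit
test; categories with expected count < 1 are pooled into `other`, and at
least two categories must survive pooling (otherwise zero degrees of
freedom — raised as an error). With only ~10 hits spread over ~20 letters
every expected count is < 1, so the comparison is only meaningful for hit
sets of several dozen genes, as the analysis scripts note when they skip it.

## Synthetic pan-genome generator

The generator emulates the cohort structure the screen assumes, not any
particular real dataset:

* **Core genome** — `n_core` clusters present in every strain (they are
  uninformative and exercise the skipping logic).
* **Accessory genome** — `n_accessory` clusters; each draws a carriage
  prevalence from a mixture (75 % uniform on (0, 1/6), 25 % uniform on
  (1/6, 1) by default, mirroring the patchwork structure of diverse
  bacterial pan-genomes where most accessory genes are rare) and then
  per-strain Bernoulli carriage at that prevalence. Note the *realized*
  carriage of a prevalence-p gene is Binomial(n, p)/n, so the realized
  rare fraction is slightly below the sampled 75 % at n = 29.
* **Planted predation genes** — each has an exact carrier count
  round(carriage_fraction·n) (configurations rounding to 0 or n are
  rejected as uninformative), carriers drawn uniformly at random — no
  phylogenetic structure, consistent with predatory phenotypes not tracking
  phylogeny in these organisms.
* **Phenotypes** — zone(strain, prey) = baseline(prey) + Σ effects of
  carried planted genes affecting that prey + N(0, noise_sd²), truncated at
  0 (truncation, not resampling: simpler and zones cannot be negative).

Defaults (29 strains, 10 prey, 100 core + 600 accessory clusters, one
planted gene per prey with 10 mm effect and carriage 1/3, baseline 20 mm,
noise 1 mm) give a cohort where each planted gene's 10 carriers dominate
their prey's superior tertile at an effect of 10 noise SDs. Everything is
reproducible bit-for-bit from the seed (`numpy.random.default_rng`).

What passing tests on this generator do **not** show: real cohorts have
phylogenetically correlated gene content (inflating false positives for
lineage-associated genes), polygenic and epistatic predation phenotypes,
assay batch effects, and draft-genome dropout of truly present genes. The
generator models none of these; recovery results here are a correctness
check of the pipeline, not an estimate of real-data power.

## Saturation analysis and power-law forecast

For each genome count G in a grid, `reps` (default 20) random strain
subsets are drawn without replacement; phenotypes are re-binarized *within
each subset* (tertiles are defined relative to the analysed strains), the
full screen is rerun, and the number of unique genes passing for ≥ 1 prey
is recorded. Uniform random subsets with replicate means are used because
a single nested chain would make grid points strongly dependent.

The mean curve is fitted by OLS of log(mean hits) on log(G) — deterministic
and exact on noiseless a·G^b data; grid points with zero mean hits are
excluded (logged). `predict_required_genomes` inverts the fit to the
smallest integer G with a·G^b ≤ target, by integer refinement around the
analytic crossing so that it is an exact right-inverse of the forward
evaluation.

Grid choice in the analysis scripts: G ≥ 15, so every subset's tertiles
have k ≥ 5 and the Fisher granularity floor (see above) does not zero out
the counts; at G ≤ 12 the screen can only pass near-perfect tables and the
curve artifactually collapses. On the default synthetic cohort the curve is
shallow (the ten planted genes pass at every G; only chance false positives
decay), so its fitted exponent is necessarily closer to zero than the steep
decay a large diverse real cohort produces; the forecasting operations are
therefore demonstrated on a published-scale fit (22601·G^−1.4), whose
crossings fall at 49 genomes for ≤ 100 candidates and 249 for ≤ 10.

## Pipeline and reproducibility

One declarative YAML config (echoed verbatim into the run directory) fixes
inputs or a simulation recipe, screen cutoffs, binarization settings,
saturation grid and seed. Stages run in order, each persisting its table,
so every number in `report.json` is recomputable from intermediates;
identical config + seed reproduces every output byte for byte. Derived
seeds (annotations: seed+1, subsampling: seed+2) keep stages independent
but deterministic. Association results are written with 12 significant
digits for reals; integer fields roundtrip exactly.

## Known limitations

* No population-structure correction (no phylogenetically aware test à la
  Scoary's pairwise comparisons); hits on structured cohorts need external
  validation.
* The screen is threshold-based; effect sizes are not estimated.
* The power-law fit is descriptive, not mechanistic; extrapolating far
  beyond the fitted grid inherits all the usual risks, and the forecast
  additionally depends on the relatedness of the genomes added.
* The traits-table dialect cannot distinguish moderate from missing; both
  read back as moderate (neither enters any contingency table).
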