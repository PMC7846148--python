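# Methods

## Scope and data model

`normevol` analyzes a genes × samples matrix of RNA-seq read counts from a
common-garden experiment: populations that evolved under different thermal
regimes (plus the reconstituted ancestral population) assayed at two
temperatures, 15 °C and 23 °C. A gene's *reaction norm* is its two-point
slope, the log2 fold change of expression at 23 °C over 15 °C; *plasticity
evolution* is a change of that slope in an evolved population relative to
the ancestral one. All inference is on model-fitted contrast estimates,
never on raw CPM differences.

## Quality control

* **Contamination screen.** Female-specific marker genes (chorion and
  yolk-protein genes in the motivating design) are quantified per library
  as `log2(1 + summed marker CPM)`; libraries above a threshold (default 8,
  log2 units) are removed. "Total log2 normalized expression" is ambiguous
  between the log of the sum and the sum of the logs; the log-of-sum form
  is the default because it is robust to zero counts and monotone in total
  marker abundance, and the sum-of-logs variant is selectable
  (`marker_statistic(..., mode="sum_of_log2")`).
* **Collapsing.** Technical libraries of the same population × temperature
  are summed into one measurement; totals are conserved.
* **Downsampling** (optional) equalizes library depth by multivariate
  hypergeometric subsampling (without replacement), preserving count
  integrality and expected proportions.
* 3′-coverage-bias screening needs alignments and is out of scope; a
  pre-computed exclusion list can be applied before loading instead.

## Normalization and filtering

TMM scaling factors are computed per library against a reference (the
library whose 75th-percentile CPM is closest to the mean of those
percentiles): per-gene log2 ratios (M) and average abundances (A) on
library-size-scaled proportions, the top/bottom 30 % of M and 5 % of A
trimmed by rank, the surviving M-values averaged with inverse delta-method
variance weights, and the resulting factors rescaled to geometric mean 1.
The implementation reproduces edgeR's `calcNormFactors(method="TMM")` to
six decimals on random instances and matches a direct-enumeration oracle to
1e-10 in the test suite.

Genes are retained when their mean CPM across all samples is **strictly
above** 1 ("above one count per million"); the filter uses raw library
sizes and precedes TMM by default (switchable), and the retained-gene count
is the enrichment background. Log-CPM, where needed, uses a prior count of
0.5.

## The negative binomial GLM

Counts are modelled `y ~ NB(mu, phi)` with `Var = mu + phi mu²` and
`log mu = X beta + log(effective library size)`.

* **Designs.** Pooled model: intercept, regime indicators, temperature
  (23 °C), regime × temperature interactions — treatment coding with the
  ancestral population at 15 °C as baseline, so every quantity of interest
  is a single linear combination of coefficients. Replicate model: the
  selection factor has one level per focal-regime replicate plus a pooled
  ancestral level (six levels for five replicates). Interaction columns
  are included only when identifiable (a group observed at both
  temperatures).
* **Fitting.** IRLS with log link, working weights `mu/(1 + phi mu)`,
  batched across all genes (one p × p solve per gene per iteration);
  relative log-likelihood tolerance 1e-8, at most 100 iterations, step
  halving when a step would decrease the likelihood; non-convergence is
  flagged, not fatal. `phi = 0` reduces exactly to Poisson regression
  (verified against statsmodels' independent IRLS to 1e-6).
* **Dispersion.** Per-gene Cox–Reid adjusted profile likelihood
  `ll(beta_hat(phi)) − ½ log det(X'WX)` evaluated on a 21-point log-spaced
  grid (1e-4 to 10) with parabolic refinement of interior maxima; a
  maximum at the lowest grid point is reported as 0. Raw estimates are
  shrunk toward a trend (the median raw phi within ~20 mean-expression
  quantile bins) with weight `df_res / (df_res + 20)` — the 20 prior
  degrees of freedom mimic standard empirical-Bayes squeezing and are
  configurable (`none` / `common` / `trend`). All-zero genes carry no
  information and receive the trend value, flagged.
* **Testing.** A contrast `c` is tested by refitting with the design
  projected onto the null space of `c` (warm-started from the full fit);
  LR = 2Δloglik referred to χ²₁, estimate reported as `c'beta / ln 2`
  (log2FC). Quasi-likelihood F-tests, voom weights and random effects are
  out of scope. BH q-values are computed per named contrast across all
  retained genes.

## Three-step plasticity analysis

1. **Plasticity calls**: within-group 23-vs-15 contrast, plastic = q < 0.05,
   positive slope = higher expression at 23 °C.
2. **Evolved expression**: evolved-vs-ancestral within each temperature,
   significant = q < 0.05.
3. **Classification** (per evolved group): candidates are genes with an
   evolved change at ≥ 1 temperature; the interaction contrast (evolved
   slope − ancestral slope) is BH-adjusted *within candidates only* (the
   restriction precedes the test, which is why the more permissive FDR 0.1
   is tolerable). Significant interaction → INCREASED if
   |evolved slope| > |ancestral slope|, DECREASED if smaller; exact
   equality (measure-zero) falls through to UNRESOLVED, the explicit
   "cannot reliably classify" class, so gene counts always reconcile:
   candidates = increased + decreased + constitutive + unresolved.
   CONSTITUTIVE requires same-sign significant shifts at both temperatures
   without interaction significance.

**False-positive guard.** A gene that truly evolved at only one temperature
can acquire spurious interaction significance from opposite-sign noise at
the two temperatures, biasing results toward increased plasticity. The
guard compares the ancestral norm with that of a hypothetical population
carrying the evolved value at one temperature and the ancestral value at
the other; that difference is algebraically the single-temperature evolved
contrast, so the guard tests those contrasts in the same BH family as the
interaction (within candidates) at the interaction FDR and passes if at
least one is significant. Under the default candidate restriction the
guard is a consistency check (candidacy already demands single-temperature
significance at a stricter FDR); with `candidate_filter=False` the
restriction is lifted and the guard does real work — the suite constructs
an opposite-sign-noise gene that is interaction-significant yet fails it.
The guard is reported post hoc by default rather than applied as a filter.

**Direction bias** is tested twice: a Wald test on the intercept of a
binomial GLM and the exact two-sided binomial test against 0.5 (the exact
test is also defined at complete separation). The test can be re-run on
ancestrally plastic genes only (|ancestral slope| > 1) to rule out floor
effects. **Sign concordance** is the Pearson χ²₁ of sign(Δ15 °C) ×
sign(Δ23 °C) on the 2×2 table of model-fitted shifts; zero shifts are
excluded and counted.

## Replicate-specific analysis

The classification pipeline is re-run per focal replicate on the six-level
design (dispersion estimated once and shared); replicates missing a
temperature are skipped with a warning. Consistency metrics, per
direction: shared-significance frequency = P(called in replicate j |
called in i) averaged over ordered pairs; and the squared Pearson
correlation of slope-change estimates across genes called in *either*
member of a pair (the most natural universe; "both" is selectable),
averaged over unordered pairs. Pairs with fewer than 3 usable genes are
skipped: a two-point r² is identically 1 and would report perfect
consistency from pure noise.

## Enrichment

Over-representation of an unranked gene list against user-supplied GMT
sets: one-sided hypergeometric upper tail with the retained genes as
background, BH across sets, enriched = q < 0.05. A ranked-list
(min-hypergeometric) statistic is deliberately not used — classification
output is a set, not a ranking. Because list length drives power, two
lists are compared by subsampling the longer to the shorter's size
(default 20 iterations, without replacement) and placing the shorter
list's enriched-set count within the subsample distribution; the
comparison p is the empirical rank `(1 + #{count_a ≤ count_b}) / (n + 1)`.

## Synthetic data

The generator draws baseline expression proportions from a log2-normal
profile (mean 4, sd 2 on the log2-CPM scale), NB counts with a decreasing
dispersion trend `phi = 0.05 + 2/CPM` (typical of bulk RNA-seq), and
uniform library sizes (8–12 M reads). Defaults mirror the emulated design:
11,200 genes, three regimes × five replicate populations × two
temperatures, ~40 % of genes ancestrally plastic with slopes ~ N(0, 1),
evolved effects planted in the hot regime only (the cold regime showed
almost no signal in the motivating study) at rates of 2 % increased,
0.75 % decreased and 0.45 % constitutive. Increased plasticity is planted
as slope magnification (default ×2) with the extra slope split as
opposite-sign shifts at the two temperatures (50/50), decreased as
attenuation (default ×0.25) split the same way, constitutive as an equal
shift (±1 log2FC) at both temperatures. Genes carrying planted
increase/decrease effects are required to have |ancestral slope| ≥ 0.5 —
magnifying a near-zero slope is undetectable in principle. Marker genes'
summed clean-library abundance is pinned at 150 CPM (log2 ≈ 7.2, just
below the screen threshold) so contamination at 16× is cleanly separable
at any gene count. Identical config + seed reproduces byte-identical
output.

What the generator does **not** emulate: between-replicate biological
heterogeneity of evolved effects (all planted effects are parallel across
replicates), batch effects, 3′ coverage bias, gene length variation, and
correlated expression between genes. Consequences worth knowing: (i)
passing recovery tests show correctness of the machinery, not robustness
to replicate-heterogeneous biology; (ii) because planted decreased effects
are parallel too, they show high cross-replicate r² — the noise-only
decreased-call scenario requires simulations with `fraction_decreased=0`;
(iii) at study-scale defaults the per-replicate increased calls include
enough noise calls that their union-universe r² is diluted well below the
pooled analysis' recovery, an honest reflection of single-replicate power
at these effect sizes.

## Problem sizes and determinism

The test suite runs simulations of 300–5,000 genes (five seeds at 5,000
genes for recovery and consistency checks) and completes in about a
minute on one core; the acceptance script runs the full pipeline at
11,200 genes in about half a minute. All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); the pipeline is
deterministic end to end, and re-running with the same configuration
produces byte-identical summaries.

## Known limitations

* χ²₁ reference for the LRT is asymptotic; with one population per level
  (replicate model) it is mildly anti-conservative, which inflates
  per-replicate call counts relative to the pooled model.
* The dispersion grid floors estimates at 1e-4 (reported as 0 at the
  boundary); extremely overdispersed genes (phi > 10) are truncated.
* FDR families are per contrast; no across-contrast multiplicity control.
* Enrichment treats gene sets as flat; no ontology structure or term
  propagation.
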