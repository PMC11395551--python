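# Methods

## Scope and data model

`aromakey` analyzes multi-group GC-O-MS studies of fermented-food
volatiles. A *study bundle* holds five plain-text tables: per-sample
peak tables (sample, replicate, retention time, detector area), an
n-alkane ladder, a compound library (name, chemical class, reference
retention index, odor threshold in water, odor descriptor), GC-O event
logs (panelist, replicate, compound or retention time, intensity 1–5,
descriptor) and QDA sensory sheets (panelist, session, six attributes,
1–5). Compound names are compared case-insensitively after whitespace
normalization, with an optional alias column for spelling variants
(e.g. "tetramethylpyrazine" for "2,3,5,6-tetramethylpyrazine").

## Identification and quantitation

Retention indices use the van den Dool–Kratz linear form
`RI = 100·(n + (rt − rt_n)/(rt_{n+1} − rt_n))` between bracketing
alkanes — the GC program is temperature-ramped, so the isothermal
logarithmic (Kováts) form would be inappropriate. Retention times
outside the ladder span are extrapolated along the nearest segment and
flagged. Peaks are assigned to the nearest library reference RI within a
tolerance (default 15 index units; ties break lexicographically so the
ranking is order-independent).

Concentrations follow the internal-standard ratio
`Cx = Ax·Cs·Vs/(As·mx)` in µg/g, with the sec-octanol spike defaults
Cs = 180 µg/mL, Vs = 5 µL, mx = 3 g. Peaks matching the internal
standard's identity are excluded from the compound table. Concentrations
are stored in µg/g and multiplied by 1000 wherever µg/kg is the natural
unit — class totals and rOAV, whose odor thresholds are µg/kg in water.
This 1000× convention is a deliberate design choice; the two units are
often mixed silently in the field's reports.

`rOAV = Ci/OTi` uses the replicate-mean concentration per sample group.
A compound without an odor threshold has an *undefined* rOAV — never
zero — and is excluded from the rOAV screen while remaining eligible for
GC-O rescue.

## Screening rules

* rOAV threshold: **inclusive** `rOAV ≥ 1` (config-switchable to a
  strict `> 1`).
* GC-O consensus: a compound counts in a sample when at least
  `gco_min_panelists` (default 2 of a 3-person panel) distinct panelists
  report it in **any** replicate session; the mean intensity averages all
  reports from detecting panelists. The "two or more" reading of a
  three-person panel is the default because a strict "more than two"
  collapses to unanimity; both are exposed in the config.
* Key compounds: `(∩ over samples of rOAV-pass sets) ∩ (GC-O consensus
  set)` — the strict all-samples reading. The unshared Venn regions are
  reported as `roav_only` and `gco_only`.
* Odor groups 1–4 (roasted/nutty, buttery/caramel, smoky/earthy,
  pungent/mushroom) are assigned by deterministic descriptor-keyword
  scoring; ties break toward the lower group and unmatched descriptors
  are flagged `unassigned`.

## Chemometrics

All latent-variable models are NIPALS fits on autoscaled data
(unit-variance by default; Pareto and centering-only available).
Component signs are fixed so the largest-magnitude loading is positive,
making every decomposition deterministic given input order.

* **PCA** — NIPALS deflation, validated against SVD to 1e-8.
* **PLS1/PLS2** — classical NIPALS with X and Y deflation;
  `B = W(PᵀW)⁻¹Cᵀ`.
* **OPLS-DA** — exactly two classes, centered 0/1 response. Variation
  orthogonal to y is removed component-wise (`w_o ∝ p − (wᵀp)w`) before
  a single predictive component; orthogonal scores satisfy `t_oᵀy = 0`
  by construction. The number of orthogonal components is chosen
  automatically: added while cross-validated Q2 improves, capped at 3.
  The shipped contrast is the first sample group against the rest
  (wild-type vs mutants), configurable.
* **Q2** — `1 − PRESS/SS` with deterministic venetian-blind folds
  (observation *i* → fold *i* mod folds; default 7 folds). Class labels
  are re-encoded per training fold, and predictions are compared on the
  raw 0/1 indicator scale.
* **VIP** — over predictive components only:
  `VIP_j = sqrt(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`, so the mean
  squared VIP is exactly 1. (Total-model VIP definitions that include
  orthogonal components exist; the predictive-only convention is used
  because VIP is interpreted against the class contrast.)
* **Permutation test** — n (default 200) uniform label permutations,
  full refit each; `p = (1 + #{Q2_perm ≥ Q2_obs})/(n + 1)`. The
  validation plot regresses permuted R2Y/Q2 on |corr(y_perm, y)| with
  the observed model anchored at correlation 1, and reports the
  intercepts. Note that the test is calibrated for an exchangeable null:
  with deterministic venetian-blind folds, a systematically blocked
  label arrangement interacts with the fold pattern, so calibration
  checks draw the label arrangement at random.
* **CV-ANOVA** — `F = (PRESS_null/df1)/(PRESS_model/df2)` with
  `df1 = n − 1` and `df2 = n − 1 − k` for a k-component model, where
  PRESS_null cross-validates the mean-only predictor on the same folds;
  p from the F distribution. A model with no components scores F = 1
  against itself; zero model residuals report F = +∞, p = 0.
* **PLSR vs sensory** — 2-factor PLS2 of key-compound concentrations
  (sample × replicate rows) against panelist-averaged attribute scores.
  Correlation loadings are Pearson correlations of each variable with
  the two factor-score vectors, drawn against circles of radius √0.5
  (50 % explained) and 1 (100 %).
* **Jack-knife** — leave-one-observation-out refits (scaling refit per
  fold, coefficients compared in original units so an exact relation has
  ~zero uncertainty); `s_b = sqrt(Σ_i g(b_(−i) − b)²)`, `g = (n−1)/n`;
  significance at `|b| > t_{1−α/2, n−1}·s_b`.

## Univariate statistics

One-way ANOVA pools the within-group mean square; Fisher-LSD tests every
pair with two-sided t-tests on the pooled MSE. By default the pairwise
tests are *protected* (they require a significant omnibus F); the
unprotected variant is a flag. Letters come from the insert-and-absorb
compact-letter-display algorithm, ordered so the highest mean carries
"a"; letter sharing exactly encodes pairwise non-significance, which the
test suite audits exhaustively. `2^−ΔΔCT` fold changes average replicate
Ct values before differencing. Hierarchical clustering uses Euclidean
distance with average linkage (scipy linkage behind the module surface)
on per-compound row-autoscaled data, with a Newick export and flat cuts.

## The synthetic-data generator

The generator emulates the study design end to end: 4 ferment groups ×
3 replicates, a 99-compound library over the study's class composition
(13 pyrazines, 19 ketones, 6 acids, 22 alcohols, 16 aldehydes,
3 phenols, plus furans/oxazoles/sulfides/esters/others), a 3-person GC-O
panel and a 10-person sensory panel over 3 sessions. The aroma-active
compounds carry their real names and descriptors; the rest of the
volatilome is synthetic filler with log-normal abundances (median
0.04 µg/g, log-sd 1.0), which puts the per-ferment grand totals near the
10⁴ µg/kg scale typical of such ferments. Reference retention indices
are synthetic placements on a 17-unit grid over RI 720–2386 (not
literature values), spaced > 2× the match tolerance so assignments are
unambiguous under the 1.5-RI-unit retention jitter.

Planted structure, fixed across seeds:

* five **marker** compounds (tetramethylpyrazine, 2,3,5-trimethyl-
  pyrazine, 2,3-dimethylpyrazine, guaiacol, 2,4,5-trimethyloxazole) are
  elevated ×1.4–1.6 in the single-knockout groups and ×2.0–2.5 in the
  double-knockout group — guaiacol's ×2.2 span is anchored to the
  roughly two-fold rOAV range such ferments show;
* 1-octen-3-ol and 3-hydroxy-2-butanone are depressed (×0.6, ×0.55) in
  the double-knockout group; 2,5-dimethylpyrazine declines mildly;
* the screening arithmetic is planted exactly: 15 compounds clear
  rOAV ≥ 1 in every group, one extra passes only in S3 and three only in
  S4 (per-group counts 15/15/16/18, union 19); 17 compounds are GC-O
  detectable (the 12 key compounds plus 5 without a full rOAV pass);
  3 of the all-group rOAV set are not sniffable (rOAV-only region);
* odor thresholds are back-derived from the planted S1 rOAV targets,
  which span ~0.3–364 for the active compounds and are drawn log-uniform
  well below 1 for filler; ~7 % of compounds get no threshold at all,
  exercising the undefined-rOAV path.

Peak areas invert the quantitation formula from true concentrations with
multiplicative log-normal replicate noise (CV 12 %, a typical
inter-replicate spread for HS-SPME-GC-MS); with zero noise the
quantitation path is the exact inverse of generation. GC-O detections
are Bernoulli per panelist × replicate with probability logistic in
`log10(rOAV × sniffability)` (midpoint 1.5 decades, slope 3); the
per-compound sniffability factor models how recognizable an odorant is
at the port and keeps the rOAV and GC-O screens correlated but not
identical, so the Venn regions are non-trivial. Sensory scores are a
linear response to odor-group log-abundance indices plus panelist noise
(sd 0.35), rounded half-up and clamped to 1–5; rounding ties are fixed
by the rule, not the seed.

`paper_fixture()` is the same generator at a fixed seed with
*expectation-thresholded* GC-O detection (a panelist logs a compound iff
its detection probability is ≥ 0.5), which makes the screening counts
deterministic by construction.

What passing the planted-truth tests does **not** show: the generator
draws compounds independently (no co-elution, no correlated matrix
effects), places retention times noiselessly enough that
mis-identification is rare, and uses a single internal-standard response
(no calibration-curve nonlinearity). Recovery rates on this synthetic
world are therefore an upper bound on what identically parameterized
real data would give.

## Numerical choices and degenerate inputs

* NIPALS convergence: squared relative step < 1e-28 (≈1e-14 in norm),
  5000 iterations max; non-convergence raises with the component index.
* Constant columns scale by 1 and are flagged rather than dividing by 0.
* Zero Y in PLS stops component extraction and yields zero coefficients.
* Zero within-group variance everywhere makes the LSD MSE degenerate and
  raises; a training fold that loses a class during cross-validation is
  skipped with a warning.
* All randomness flows from a single seed (`numpy.random.default_rng`);
  identical (inputs, config, seed, row order) give byte-identical
  outputs, which the test suite checks by hashing result directories.

## Problem sizes used by the checks

The test suite and the acceptance script run at the study's native scale
(99 compounds, 4 × 3 observations) and validate stochastic claims at
moderate replication chosen to keep the whole suite in a few minutes:
oracle equivalence on 100 random matrices, permutation calibration with
200 outer replicates of 50 permutations, null-Q2 medians over 100 seeds,
and planted-truth recovery over 20 seeds (10 in the acceptance script).

## Known limitations

* OPLS-DA supports exactly two classes (the wild-type vs mutants
  contrast); multi-class designs need one-vs-rest runs.
* The numbers are not intended to reproduce any proprietary software
  bit-for-bit; SIMCA-style conventions (unit-variance scaling, 7-fold
  venetian blinds) are followed where a choice was needed.
* Identification is retention-index-based only; no mass-spectral
  matching is modeled.
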