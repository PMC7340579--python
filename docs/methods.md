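# Methods

## Composite quality scores

Each quality metric is converted to a tie-averaged percentile rank within
its molecule group: deposits are ranked 1..N from worst to best (all five
metrics are "badness" measures, so lower raw values rank higher), tied
values receive the average rank of their group, and rank r maps to
100·r/N. This "inclusive" convention places the unique best deposit at
exactly 100 and gives every population the mean 100(N+1)/(2N); a
"midpoint" convention, 100·(r−0.5)/N, is available behind the
`convention` flag wherever percentiles are computed. The mean law and a
brute-force counting definition of the percentile are asserted in tests.

The protein-group composite averages the percentiles of R_free, RSRZ
outliers, and the first principal component of the geometry metrics; the
nucleic-acid composite substitutes the clashscore percentile for the PCA
term, since Ramachandran and rotamer outliers are undefined for nucleic
acids. Protein–nucleic-acid complexes are scored in the protein group: all
five metrics exist for them. The minimum variant replaces the mean of the
three components by their minimum and is therefore pointwise ≤ the
averaging variant. The final quality percentile P_Q1 re-ranks the
composite within the molecule group, so the protein and nucleic reference
populations never mix.

## Geometry PCA

The three geometry metrics (clashscore, Ramachandran outliers, rotamer
outliers) are standardised to zero mean and unit variance and decomposed
by an eigendecomposition of their covariance matrix. Deposits with rotamer
outliers > 50%, Ramachandran outliers > 45%, or clashscore > 250 are
excluded from the *fit* only — extreme values would otherwise dominate the
covariance — but are scored like any other deposit with the fitted
standardisation and loadings. PC1 is oriented so its loadings are
non-negative (larger PC1 = worse geometry); since the three metrics are
positively correlated badness measures, this orientation is always
attainable by a global sign flip, fixed deterministically by the sign of
the loading sum. Remaining components get their largest-magnitude loading
positive, again only for determinism. Because the PC1 loadings come out
nearly equal, an equal-weight PCA-free approximation —
(P_Rfree + P_RSRZ + (P_Clash + P_Rama + P_Rota)/3)/3 — tracks the exact
composite closely (Spearman ρ > 0.95 on synthetic protein data); the
exact PCA form remains the default because the loading equality is an
empirical accident, not a guarantee.

## Time- and resolution-conditioned percentiles

P_Q1(t) is the percentile of a deposit's composite within the population
of same-group deposits with a strictly earlier deposition date, plus the
deposit itself; including the deposit makes the score well defined for the
first deposit of a group (it scores 100) and is the package default, with
an exclude-self mode behind a flag. Deposits sharing a date are excluded
from each other's reference populations: they are scored against the
pre-date state of the archive, then merged. P_Q1(t,d) additionally
restricts the population to the deposit's resolution bin — resolution
rounded half-up to 0.1 Å and clamped into [1.0, 4.0] Å. Dates with only
year precision order by year, with the PDB id as a deterministic
processing tie-break.

The composite Q1 itself is computed once from the full-dataset component
percentiles; only the final percentile is re-ranked within the temporal
population. Recomputing component percentiles inside every historical
population would cost O(N²) population builds and would make a deposit's
score depend on which snapshot generation it was scored in; the one-pass
design keeps scores prefix-stable (future deposits never change past
scores), which is asserted by test against an O(N²) brute-force
re-ranking.

The sweep maintains one sorted score pool per (group, bin) and inserts
each date cohort after scoring it, so the whole computation is a single
chronological pass.

## Missing-data imputation

Three methods fill missing metrics: column mean, column median, and
chained equations (MICE) with a Bayesian ridge regressor, delegated to
scikit-learn's `IterativeImputer`. The chained scheme initialises holes
with column means, then repeatedly regresses each incomplete column
(most-missing first) on all others — the five metrics plus the
always-present supporting variables R, resolution, and deposition year —
and replaces holes with posterior-mean predictions; the default is 10
cycles with an early stop when imputed values change by < 1e-4.
Predictions use the posterior mean, not posterior draws, so results are
deterministic given the seed. Imputed values are clipped into legal
ranges: clashscore ≥ 0, outlier percentages [0, 100], R factors (0, 100).
Observed cells are never modified; inapplicable cells
(Ramachandran/rotamer for nucleic acids) are excluded from fitting and
never filled, which is why protein-group and nucleic-acid deposits are
imputed as separate blocks with different column sets. A single completed
dataset is produced (no multiple-imputation pooling) because downstream
ranking consumes the completed values directly.

## Imputation evaluation

The harness takes the complete portion of a dataset (all applicable
metrics plus R observed), hides observed cells, imputes with every
candidate method on the identical mask, and scores predictions at the
hidden cells with three error measures: MAE (mean |error|), RMSE, and
MAD. MAD is defined as the median absolute error median(|truth −
imputed|) — an error magnitude on the same scale as MAE — rather than the
dispersion-about-median form; both conventions are implemented behind
`mad_convention`, since the name is ambiguous in the field.

Masking defaults to independent per-metric Bernoulli draws at the
archive's missingness rates, under which the fraction of deposits losing
at least one metric is emergent (≈ 1 − Π(1 − p_m)). Real archives
concentrate missingness on a subset of deposits (early structures lack
several metrics at once), so the any-missing fraction can be smaller than
independence predicts; passing `target_any_fraction` activates a joint
scheme — deposits are selected at the any-missing rate, and conditional
per-metric mask probabilities are solved by the fixed point
c = 1 − Π(1 − p_m·c/a) so the per-metric marginals still hold exactly in
expectation. The exactness argument assumes a homogeneous population (one
molecule group); with mixed groups the inapplicable-column correction
introduces a small bias in the protein-only metrics.

Repetitions are paired (every method sees the same mask), which makes
them valid blocks for a Friedman rank test per (metric, error measure),
with methods as treatments. The Nemenyi post hoc compares rank-mean
differences against the studentized-range distribution — implemented
directly from that distribution since no post hoc package is a package
dependency — and is cross-checked in tests against total-dominance and
null scenarios.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed at the archive-wide study conditions:

- **Marginals** (mean/SD): clashscore 8.05/9.11, Ramachandran outliers
  0.49/1.26, rotamer outliers 3.26/3.65, RSRZ outliers 4.05/4.06, R_free
  23.35/3.82, R 19.31/3.25 — matched exactly via moment-matched lognormals
  for the non-negative right-skewed metrics and Gaussians for the R
  factors.
- **Missingness** (fractions): 0.0010 / 0.0169 / 0.0172 / 0.0956 / 0.0429,
  R 0.0239, with RSRZ missingness up-weighted 4× before 1995 (renormalised
  to keep the overall rate) to mimic the metric's late introduction;
  resolution and year are never missing.
- **Dependence**: a Gaussian copula on a per-deposit latent quality. The
  latent combines a year trend (default +0.03 SD/year — quality improves
  over time), a resolution penalty (−0.8 SD/Å — lower-resolution data
  yield worse models), a per-journal offset (SD 0.2), and unit Gaussian
  noise, standardised empirically. Each metric loads on the latent with
  weight 0.65 by default (the archive publishes no inter-metric
  correlation matrix, so the loading is a free, documented parameter);
  R and R_free share an extra common factor so their correlation hits the
  configured 0.9.
- **Population structure**: 6% nucleic-acid-only deposits (their
  Ramachandran/rotamer cells are inapplicable), 5% complexes, 16%
  "To be published", 9% structural-genomics flags, 40 journals with
  Zipf-like sizes, resolution from a year-conditioned lognormal centred
  near 2.13 Å.

All draws are made independently of the journal offsets, so
`inject_journal_effects` regenerates metric values under new offsets while
reproducing ids, dates, assignments, and missingness bit-identically —
the mechanism behind the parameter-recovery tests.

The generator does **not** emulate the archive's growth curve, per-journal
historical volumes, heavy-tailed journal-size dynamics, or the correlated
joint missingness of early deposits (missingness is independent per
metric). Passing tests on synthetic data therefore demonstrate the
correctness and calibration of the machinery — percentile laws, causality,
recovery of injected effects — not the historical numbers of the real
archive, which depend on its particular joint distribution.

## Journal analytics

Rankings average a chosen temporal percentile per canonical journal over
deposits citing it, with an eligibility threshold (default 100 structures
all-time, 30 per 5-year window; windows are anchored so the last one ends
at the dataset's final year). Welch's t-test compares each journal's
deposits against the complement (all other deposits, not the full archive
including the journal — the two samples must be independent), two-sided,
with Bonferroni correction α/k over the k journals tested at α = 0.001.
Ranks are dense. Mean resolutions are reported three ways: arithmetic,
geometric exp(mean log d), and the Å⁻³ power mean (mean d⁻³)^(−1/3),
which the power-mean inequality orders V ≤ G ≤ arithmetic.

Quality–impact correlation: for each calendar year, each journal with at
least 5 deposits that year (configurable; deposition year is used, as
publication year is not in the data model) contributes one point (impact
indicator, mean temporal percentile); Spearman's ρ is computed per year
for IPP and SNIP, with ρ undefined below 3 points.

Journal-name cleaning case-folds and strips punctuation, applies an
optional user-supplied alias table (raw → canonical, optional ISSN), and
maps absent citations to the "To be published" placeholder; canonical
names map to themselves, making cleaning idempotent.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic populations of
2 000–30 000 deposits — large enough for the binomial/SE-based calibration
checks (3-SE bands) and small enough for interactive runs. Imputation
evaluation uses 20–100 repetitions depending on the check. Brute-force
oracles (O(N²) temporal re-ranking, counting-definition percentiles,
direct eigendecomposition) back the fast paths at N ≤ 2 000. Degenerate
inputs fail loudly: empty populations, fully-missing columns,
zero-variance geometry metrics, non-positive resolutions, and undated
deposits are errors, not silent defaults. The chained-equations stage
falls back to column means (logged) only if the regression design is
degenerate.

## Known limitations

- Percentile conventions: whether the real archive's published scores use
  the inclusive or midpoint convention, and whether a deposit is included
  in its own temporal reference population, are open conventions; both
  are implemented behind flags with the defaults documented above.
- The alias table shipped is empty; reproducing a specific archive's
  canonical journal count requires the user's own curation CSV.
- Single imputation only; no uncertainty propagation from imputed cells
  into the rankings.
- The impact correlation matches deposits to indicators by deposition
  year; structures published long after deposition are matched to the
  wrong indicator year.
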