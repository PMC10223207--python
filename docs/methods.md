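# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Two-level abundance quantification

The combined RP-HPLC / SDS-PAGE quantification model assumes that (i)
chromatographic peak areas are proportional to the protein mass eluting in
each fraction, and (ii) within a fraction, gel-band optical densities are
proportional to the mass of each band. A fraction's percent of total venom
protein is therefore `100 · peak_area / Σ peak_areas`, and a band's percent
is the fraction percent times `density / Σ lane densities`. Fractions with
a single band ("whole" fractions) skip the second level. Band percents are
accumulated per protein family; by construction the output sums to 100%
(asserted to 1e−9). All-zero peak areas, or an all-zero lane in a banded
fraction, are rejected as invalid input rather than silently treated as
zero mass.

## Abundance tables and missing entries

Tables hold percentages in [0, 100] with missing entries (a family not
detected in a venom) allowed; per-taxon sums may not exceed 100 plus a
0.5-point tolerance for accumulated rounding in published tables. The
default missing policy treats missing as 0% for means, SDs, CVs and
dominant sums — a family not detected contributes zero abundance — which
is what reproduces the published cross-taxon variability range on the habu
table. An `exclude` policy (drop missing entries from the sample) is
available but non-default.

Sample statistics use the n−1 denominator throughout. Published-style
rounding (half away from zero at 1–2 decimals) is applied only when
formatting reported values, never inside computations.

The packaged habu table keeps the Taiwan *P. mucrosquamatus* sample and the
subadult *P. mangshanensis* as their own rows. The taxon-set constants in
`venomics.datasets` encode the analysis conventions: the five
currently-quantified adults for the dominant-family summary, eight adults
(mainland *P. mucrosquamatus*; Taiwan sample and subadult excluded) for the
CV analysis, and nine taxa for the signal-trait filter.

## Similarity, breadth and trait filtering

The protein similarity coefficient is a Sørensen–Dice percentage on
protein-identifier sets. What counts as "the same protein" across venoms
is an open judgement call in practice, so the identity criterion is an
injectable key function (default: exact identifier match); the packaged
pairwise matrix is data, not something recomputable from identifiers.

Venom breadth is the standardized Levins index over a fixed category set.
The category set defaults to all families present in the profile, but for
cross-taxon comparability callers should pass the full family list so every
taxon is scored over the same categories; the result is invariant to
rescaling the profile.

The signal-trait filter retains families whose abundance strictly exceeds
1% in at least five taxa (both thresholds configurable). Strict inequality
means a family sitting exactly at 1% everywhere is excluded.

## Tree handling and independent contrasts

Newick parsing and serialization are delegated to dendropy; the wrapper
validates unique tip labels and nonnegative branch lengths. The Brownian
covariance matrix V has V[i,i] = root-to-tip depth and V[i,j] = depth of
the most recent common ancestor; no ultrametricity is assumed.

Contrasts follow the standard pruning recursion: each internal node takes
the variance-weighted average of its daughters, the contrast variance is
the sum of (adjusted) daughter branch lengths, and the parent edge is
extended by v₁v₂/(v₁+v₂). Polytomies are resolved deterministically
left-to-right into zero-length bifurcations, so an n-tip tree always
yields n−1 contrasts; the VCV route needs no resolution. A contrast whose
combined daughter branch length is exactly zero receives an epsilon of
1e−8 × tree depth, with a logged warning.

Because the standardized contrasts are a fixed linear map of tip values,
the map is exposed as a matrix; the permutation test below computes all
replicates as one matrix product.

## Blomberg's K and the permutation test

K is the ratio of the observed MSE₀/MSE (ordinary over phylogenetically
corrected mean squared error around the GLS mean) to its Brownian-motion
expectation on the same tree. It is exactly 1 on an equal-depth star tree,
invariant to affine trait transforms and to global branch-length
rescaling, near 1 for Brownian traits and near 0 for phylogeny-free
traits. V is inverted through a Cholesky factorization; if factorization
fails, a jitter of 1e−10·tr(V)/n is added to the diagonal once, logged,
before giving up.

The permutation statistic is the variance of the standardized independent
contrasts — the statistic of the comparative-methods routine family this
implementation mirrors, and the one whose observed value shrinks under
phylogenetic structure. The null shuffles trait values uniformly over
tips; p = (#{statistic_perm ≤ statistic_obs} + 1)/(reps + 1), so the
smallest attainable p is 1/(reps+1). A phylogenetically-corrected-MSE
statistic is available behind a flag. One seeded generator drives each
test invocation, and `multi_phylosignal` reuses the same seed per trait so
identical traits give identical results; LD50-style function traits enter
untransformed by default.

The default 1000 replicates put the p-value floor at ~0.001; tests and
calibration checks in this repository use 100–200 replicates where only
rates or determinism are at stake.

## Spearman–Karber LD50

Mortality proportions are smoothed to a nondecreasing sequence by
group-size-weighted PAVA (scipy's isotonic regression), then treated as a
piecewise-linear tolerance CDF on the log10-dose scale. The point estimate
is the mean of that distribution; with trimming (default 0%, conventional
10% available) both tails are cut at the trim level and the central curve
rescaled before integrating. Doses are log10-transformed — the convention
of the classical program — and the point estimate is base-invariant.

If the smoothed curve never brackets 50% mortality the estimator refuses
(non-bracketing error). If it brackets 50% but does not reach 0 or 1,
virtual anchor doses one log-step outside the tested range complete the
curve; anchors are exact and contribute no sampling variance. The variance
of the log-LD50 uses the delta method with the PAVA pooling held fixed:
Var = Σ (∂L/∂pᵢ)² pᵢ(1−pᵢ)/(nᵢ−1), the derivatives obtained by central
finite differences of the trimmed-mean functional (for trim 0 this is the
textbook closed form with weights ((xᵢ₊₁−xᵢ₋₁)/2)²). The nᵢ−1 denominator
follows the classical trimmed program; nᵢ = 1 falls back to nᵢ. The 95% CI
is 10^(log-LD50 ± 1.96·SE).

## Synthetic data

All generators use NumPy's `default_rng` (PCG64), pinned as the package's
generator algorithm so seeded fixtures are stable.

- **Yule trees** start from two lineages; inter-event waits are
  Exponential(k·λ), a uniformly chosen lineage splits, and the final
  segment runs one more exponential wait, giving expected depth
  Σ_{k=2..n} 1/(kλ). Trees are ultrametric with tips labelled in birth
  order.
- **Brownian traits** are drawn from N(0, σ²V) via Cholesky (a 1e−12
  diagonal guard covers degenerate trees); **white-noise traits** are
  i.i.d. N(0, σ²).
- **Venom profiles** are 100 × Dirichlet draws. The default concentrations
  give SVMP/PLA2/SVSP dominance with minor and trace families, echoing the
  marginal pattern of real habu tables — a qualitative shape, not a fitted
  model.
- **Quantification records** invert the two-level abundance formula
  exactly: family masses are split into random parts, parts are dealt into
  whole and banded fractions, and areas/densities are rescaled per
  fraction and lane. Recovery through the quantification path is exact by
  construction, which is what makes it a round-trip oracle.
- **Dose–mortality series** draw Binomial(n, Φ(slope·(log₁₀d − log₁₀LD50)))
  deaths, so the death probability at the true LD50 is exactly 0.5. The
  default simulated design (six two-fold dose steps spanning the true
  LD50) mirrors a typical small-animal lethality assay; recovery checks
  use n = 10 per group to keep the estimator's discreteness mild.

What the generators do not emulate: chromatographic peak overlap or
detection limits, gel saturation and staining nonlinearity, mass-spectral
identification errors, non-Brownian trait evolution (selection, rate
shifts), or litter/cage effects in mortality data. Passing tests therefore
validate the arithmetic and statistical machinery on clean inputs, not
robustness to instrument artifacts.

## Problem sizes in the checks

The repository's verification suite uses 20-tip trees with 200 Brownian
replicates for K recovery, 500 white-noise traits at 200 permutation
replicates for type-I-error calibration, 500 simulated dose series for
LD50 recovery, and 100 random profiles for the quantification round trip —
sizes at which the Monte-Carlo error of each rate or mean is well inside
the asserted bands while the whole suite runs in seconds.

## Limitations

- The published per-family K values ship as data; the underlying Bayesian
  tree is not redistributable, so K is validated against exact identities,
  invariances and simulation recovery rather than against those numbers.
- The published pairwise PSC matrix likewise cannot be regenerated without
  the original identifier lists and matching criterion.
- The trimmed-variance formula treats the isotonic pooling as fixed, which
  slightly understates uncertainty for heavily non-monotone data.
- Compositional traits are analyzed as raw percentages (no log-ratio
  transform), matching the analysis convention this package reimplements.
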