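# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical conventions, and the design choices made where the published
analysis recipe leaves the details open.

## Preprocessing

A spectrum is a strictly monotone ppm axis with intensities (stored
ascending; descending input is accepted and flipped). Bucketing integrates
the piecewise-linear spectrum exactly (trapezoidal quadrature on the union
of the sampling grid and the bucket edges) over left-closed, right-open
intervals of width 0.004 ppm tiling [0.5, 9.0). This makes bucket values
independent of the sampling grid and conserves the total integral to
floating-point accuracy. Buckets whose *centers* fall inside the
residual-water window δ 4.20–5.20 (inclusive) are discarded: 250 of the
2125 buckets, leaving 1875.

**Order of operations** is fixed as bucket → exclude → normalize, i.e. row
normalization runs over retained buckets only. The alternative order
(normalize, then exclude) yields rows that no longer sum to one and lets
imperfect water suppression distort every other bucket's share; a
regression test pins the chosen order. Total-integral normalization divides
each row by its own sum (requires strictly positive sums); wet-weight
normalization divides by the sample weight in grams (weights carried in
mg). Chemical-shift referencing is assumed already applied upstream; a
constant-offset re-reference utility exists but is off by default.

Note that total-integral normalization is a closure transform: a genuine
decrease of a dominant signal (e.g. lipid) mechanically inflates the
normalized share of every other bucket. Regional effect signs on
closure-normalized data therefore mix true concentration changes with
compositional artifacts — one reason recovery tests run on extract-mode
data (see below).

## PCA and OPLS-DA

PCA is computed by SVD of the mean-centered matrix; explained-variance
fractions are squared singular values over their total. Component signs are
fixed by making the largest-magnitude loading entry positive.

OPLS-DA uses the single-response orthogonal-projections algorithm: with X
unit-variance scaled and y ∈ {0,1} centered, w ∝ X′y (normalized, computed
once); each orthogonal component then takes t = Xw, p = X′t/t′t,
wₒ ∝ p − (w′p)w, tₒ = Xwₒ, pₒ = X′tₒ/tₒ′tₒ and deflates X ← X − tₒpₒ′.
The final predictive score is t = Xw on the deflated matrix with
b = t′y/t′t. Because y is a single column, no NIPALS iteration is needed —
the solution is closed-form; with zero orthogonal components it coincides
with one-component PLS1 (verified against an independent implementation in
the tests). Prediction applies the stored scaling, filters new data through
the stored (wₒ, pₒ) sequence, and returns b·(Xw) + ȳ on the 0/1 scale; hard
class calls threshold at 0.5 (the centered midpoint). Conventions: the
predictive score is signed to correlate positively with y; zero-variance
buckets are dropped with a warning before scaling (they cannot be
unit-variance scaled); R²X splits exactly into predictive + orthogonal +
residual fractions because all score vectors are mutually orthogonal.

The orthogonal-component count defaults to 1; `choose_n_ortho` offers
Q²-guided selection (stop when the gain drops below 0.01). The original
analysis does not report component counts, so this is a substitute policy,
not a reproduction.

## Cross-validation, CV-ANOVA, ROC

Folds are stratified by class: within each class, indices are shuffled by a
seeded RNG and dealt one at a time to the least-filled fold (ties to the
lowest index). This keeps folds balanced overall and within class,
degrades gracefully when a class has fewer members than K, and reduces to
leave-one-out at K = n. For each fold, the scaling parameters *and* the
model are refit on the training portion only — held-out samples never
touch the training statistics (a leakage test pins this). Q² = 1 −
PRESS/SS_tot with PRESS pooled over folds and SS_tot about the global mean.

CV-ANOVA: F = ((SS_tot − PRESS)/df₁)/(PRESS/df₂), df₁ = model parameter
count, df₂ = n − df₁ − 1, upper-tail p from the F distribution. The
parameter count convention is 1 (predictive component) + 2·n_ortho (each
orthogonal score/loading pair) + 1 (intercept); this follows the
component-counting spirit of the CV-ANOVA method and is pinned by a
regression test as a convention. F is floored at 0 (p = 1) when PRESS ≥
SS_tot; PRESS = 0 pins p = 0.

**Known limitation — CV-ANOVA is conservative.** Under a permuted-label
null, cross-validated predictions are slightly anti-correlated with the
labels, so PRESS typically exceeds SS_tot and the test almost never
rejects (measured null rejection rate ≈ 0 at α = 0.05; ~74% of null
permutations hit the F = 0 floor). CV-ANOVA p-values are therefore
trustworthy when significant but are not calibrated to the nominal α under
the null; they should be read as a screening criterion (as in the original
workflow's p < 0.05 gate), not an exact test.

ROC curves come from the cross-validated predicted y values; thresholds
sweep the unique scores and the trapezoidal AUC equals the midrank
Mann–Whitney statistic (tested against an exhaustive pair count). A single
operating point is reported at the Youden-J maximum.

## Correlation loadings and cutoffs

For each bucket j, r_j is the Pearson correlation of the raw bucket values
with the predictive score t, and the plotted coefficient is
cov(centered bucket, t)/sd(t) — "back-scaled" out of the unit-variance
metric so strong peaks dominate the trace like a spectrum. r is computed
against t rather than raw y: for a two-class y they are monotonically
related, and t is what the discriminant actually uses. Significance uses
the critical Pearson correlation r_crit = t*/√(t*² + n − 2) with t* the
two-sided (1−α) Student-t critical value on n−2 df. Display values are
**truncated** (floored toward zero) at two decimals, not rounded —
rounding would print 0.30/0.40 where the conventional thresholds for
n = 44/25 are 0.29/0.39. Full precision is used internally. Coefficient
plots color by |r| (warm = significant); |r| rather than r² is a
documented choice.

The change table reports, per metabolite, the strongest-|r| significant
bucket within that metabolite's ppm regions (shipped as an editable CSV of
38 resonance assignments); metabolites with no significant bucket are "ns",
and metabolites whose regions fell entirely in the excluded water window
are "not_evaluable" rather than silently ns.

## Fatty-acid analytics

Species names follow Cx:ynZ notation and are parsed into saturation class
(0 double bonds → SFA, 1 → MUFA, ≥2 → PUFA) and n-family. Molar
percentages are 100·c/Σc per sample; class percentages sum member species,
so SFA + UFA = 100 and MUFA + PUFA = UFA by construction. The delta-6
desaturase (D6D) index is the product/precursor concentration ratio
C18:3n6/C18:2n6 — the standard estimated-desaturase-activity convention;
the downstream-product variant C20:3n6/C18:2n6 is available behind a flag.
The index is reported missing (NaN) when the precursor is absent or zero.
Group comparisons are pairwise Student's t-tests (Welch behind a flag) on
every species and class feature with per-feature flags at α = 0.05 and no
multiple-testing correction by default, matching per-feature reporting
practice; Benjamini–Hochberg flags are available behind a flag. GSH/GSSG
tables are compared the same way.

## Synthetic data

The generator emulates the statistical structure of a three-group
clinical cohort (defaults 46 healthy adjacent / 25 benign / 28 malignant,
the published design):

- **Spectra** are sums of Lorentzian lines (HWHM 0.003 ppm default) from a
  built-in library of 28 metabolites at standard chemical shifts, plus
  i.i.d. Gaussian point noise (sd 2.0 against peak heights of order 10²,
  i.e. ~1% noise — resolved-spectrum conditions). Metabolite levels are
  log-normal across samples (σ = 0.2, ~20% biological CV) around
  group-specific medians.
- **Planted effects** multiply group medians by (1 + magnitude); the default
  magnitude 0.5 and the default sign pattern follow the reported
  discrimination structure (lesions: lactate, amino acids,
  choline-containing compounds, taurine, inositols, glutathione, fumarate
  up, lipid down; malignant vs benign: phospho-cholines, lactate, branched
  amino acids up; citrate, inositols, nucleosides down). Effect sizes are
  chosen for testability — the source analysis reports only signs and
  correlations, not magnitudes.
- **Intact vs extract mode**: intact mode adds broad lipid envelopes at
  δ 0.90/1.30/2.02/5.33 (width ×20); extract mode omits them and carries
  per-sample wet weights (default uniform 40–60 mg around the ~50 mg
  protocol amount), with signal scaled by tissue mass so wet-weight
  normalization has something real to undo.
- **Determinism**: one RNG sub-stream per sample derived from the config
  seed; identical configs give bit-identical outputs.
- **Fatty acids / GSH**: log-normal concentration tables around realistic
  soft-tissue medians (palmitate/oleate dominant), with default planted
  shifts mirroring the reported composition pattern and a GSH elevation in
  both lesion groups with null GSSG.

What a green recovery test establishes — and what it does not: the
generator produces resolved, baseline-free, drift-free spectra with
independent Gaussian noise and log-normal levels. Passing recovery tests
shows the pipeline correctly extracts planted structure under those
assumptions; it says nothing about peak misalignment, baseline error,
phasing artifacts, or metabolite correlation structure in real tissue.
Regional sign recovery is scored on **extract-mode** data: in intact mode
the broad lipid envelope (planted down in lesions) overlaps the δ 0.9–1.3
and 2.0 regions and dominates the regional correlation signs of
co-resonant metabolites — the same signal-overlap problem that motivates
analyzing tissue extracts in practice. This is a physical property of
overlapped spectra, not a pipeline defect; intact-mode change tables should
be read per-resonance, not per-metabolite, in crowded regions.

## Degenerate inputs and tolerances

- Bucket/exclusion boundary comparisons use a 1e−9 ppm tolerance.
- Exactly constant matrices raise zero-variance errors; identical rows with
  numerical jitter fit cleanly (PCA scores ~0).
- Zero-variance buckets: dropped before OPLS-DA scaling (warning); reported
  as r = 0 with an explicit flag in loadings reports.
- Orthogonality and partition identities hold to 1e−8; scaling round-trips
  to 1e−10; AUC matches the pair count to 1e−12.
- Exclusion regions that remove every bucket, coverage shortfalls,
  non-monotone axes, single-class labels, K > n, df₂ ≤ 0 and unparseable
  species names all raise typed exceptions rather than propagating NaNs.
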