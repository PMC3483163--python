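# Methods

This document records the statistical models, the numerical choices behind
them, and the scope of the synthetic-data generator.

## Study design being modeled

A pedigree-based cytotoxicity study: lymphoblastoid cell lines from 17
extended families (6–10 members each, ~55 lines assayed for expression,
nearly all members assayed for drug response), treated with two drugs
(imatinib, a targeted kinase inhibitor, and omacetaxine, a general protein-
synthesis inhibitor). The analysis chain is:

1. alamarBlue absorbances → percent viability → 4PL dose–response fits →
   inhibitory concentrations (IC10–IC90) and the SDR slope per line.
2. Heritability of log IC doses via a polygenic variance-component model on
   the pedigree kinship matrix.
3. Expression arrays → quantile normalization → per-line log2 fold changes
   (treated vs untreated) → kinship-corrected per-probe mean tests → BH FDR
   → k-means clustering in the (iFC, oFC) plane → fold-change/SDR
   association.
4. qPCR validation via 2^−ΔΔCT and platform concordance.

## Viability

Percent reduction of alamarBlue uses the molar extinction coefficients of
the oxidized dye:

    v = 100 · (117216·A570,test − 80586·A600,test)
            / (117216·A570,untr − 80586·A600,untr)

Replicate wells are averaged on the absorbance scale *before* the equation.
Note that some descriptions of this assay label the two coefficients'
wavelengths the other way around in prose; this implementation follows the
displayed equation (117,216 multiplies the 570 nm absorbance).

## Dose–response

The 4PL curve in log10 dose x is

    v(x) = bottom + (top − bottom) / (1 + 10^(hill·(x − log10 IC50)))

with hill > 0 (viability decreases with dose). Fitting is bounded
least-squares (`scipy.optimize.least_squares`, TRF) over a deterministic
multi-start grid (7 log-IC50 candidates spanning the dose range × hill ∈
{0.5, 1, 2}), followed by an unbounded Levenberg–Marquardt polish kept only
if it improves the residual while staying in bounds. IC_x is the closed-form
inversion of the fitted curve at target viability 100 − x; targets outside
(bottom, top) are unattainable and raise an error. SDR is the OLS slope of
viability on log10 dose — a crude summary by design (it is what the study
design prescribes), invariant to dose-unit changes.

## Polygenic variance-component model

For trait y on n pedigree members with relatedness matrix 2Φ:

    sporadic:   y = m + Xβ + e,        e ~ N(0, σ²e·I)
    polygenic:  y = μ + Xβ + g + e,    g ~ N(0, σ²g·2Φ)

h² = σ²g/(σ²g + σ²e). Fitting is full maximum likelihood. One
eigendecomposition 2Φ = U Λ Uᵀ rotates the model to independent
coordinates; at fixed h² the weighted-least-squares profile gives (μ, β)
and the total variance in closed form, so the likelihood is maximized over
the single parameter h² ∈ [0, 1−10⁻⁶].

Optimizer policy (deliberate): a coarse grid {0, 0.1, …, 0.9} followed by
bounded Brent refinement in the bracket around the best grid point; the
bracket extends to the upper clamp only when 0.9 itself is best. A pedigree
containing an exact monozygotic twin pair makes 2Φ singular (one zero
eigenvalue, the co-twin difference contrast), and the ML profile likelihood
then diverges as h² → 1 whenever a fixed effect can interpolate that
contrast — a classic unbounded-likelihood degeneracy, not an optimizer bug
(verified against a fine-grid search). The local-search policy deliberately
does not chase that clamp-dependent spike; reference variance-component
tools behave the same way. REML would remove the degeneracy but the model
here is full ML.

Nested test fits (full vs constrained) exchange their fitted h² values as
search hints (`_nested_polygenic_pair`) so both land on the same likelihood
mode and the LRT statistic is guaranteed non-negative.

### Covariates

The fixed-order covariate set is age, sex, age×sex, age², age²×sex
(sex coded 1 = male). The stored covariate values are the literal products;
**inside the fitter the columns are mean-centered**. This deviates from a
"use the raw products" reading on purpose: uncentered age/age² columns
nearly span the constant vector, so a no-intercept constrained model could
absorb any mean shift and the mean-fold-change test would lose essentially
all power. Centering leaves every coefficient and coefficient test
unchanged while making the intercept the covariate-adjusted mean, which is
the quantity the constrained model must pin at zero.

### Tests

- Heritability: LRT of polygenic vs sporadic. σ²g = 0 is on the boundary of
  the parameter space, so the null reference is the 50:50 mixture of a point
  mass at 0 and χ²₁; a statistic of exactly 0 gives p = 0.5. Traits are
  rank inverse-normal transformed first (Blom offset: Φ⁻¹((r − 3/8)/(n + ¼)),
  average ranks for ties).
- Mean fold change: the full model estimates the covariate-adjusted mean
  freely; the constrained model fixes it at 0. Interior parameter → plain
  χ²₁. Available with and without the kinship covariance.
- FC–SDR association: fold change enters the polygenic model of SDR as an
  extra (centered) covariate; its coefficient is tested against 0, plain χ²₁.

## Expression

Quantile normalization maps each sample column onto the mean empirical
distribution (average ranks for ties, linear interpolation at fractional
ranks); after normalization all column sorted vectors are identical.
Intensities are floored at 1.0 before log2 ratios so fold changes stay
finite on background-subtracted data.

## Multiple testing and clustering

BH step-up q-values come from `statsmodels.stats.multitest` (`fdr_bh`).
k-means (k = 4 by default) uses `sklearn.cluster.KMeans` with Lloyd
refinement, seeded random initialization and 100 restarts, so results are
deterministic given the seed. Confidence ellipses use the sample covariance
eigendecomposition with semi-axes √(λᵢ · χ²₂,level). Kruskal–Wallis and the
one-sample proportion χ² wrap `scipy.stats`.

## qPCR

Triplicate CT values are accepted if their SD (n−1 denominator) ≤ 0.3;
otherwise the tightest pair is tried, and the sample is excluded if that
also exceeds 0.3. ΔΔCT assumes perfect doubling: rq = 2^−ΔΔCT. Platform
concordance uses Pearson when both margins pass Shapiro–Wilk at 0.05 and
Spearman otherwise.

## Synthetic-data generator: scope

Every generator is a pure function of (config, rng). The defaults *are* the
study conditions: 17 families of 6–10, 55 assayed lines containing sibling
pairs, first-cousin pairs and exactly one MZ pair; IC-trait heritability
0.60 (imatinib) and 0.0 (omacetaxine); dose grids 2–200 µM (imatinib) and
5–500 nM (omacetaxine); planted four-cluster (iFC, oFC) structure at the
printed cluster centers with ~9% of probes non-null.

Absorbances are synthesized at the plate level (untreated wells at
(0.8, 0.4); treated wells solve the viability equation for A570) so the
Eq.-style viability code is exercised and the noiseless pipeline inverts the
generator exactly. Per-probe fold-change heritability is drawn uniformly
from a configurable interval. The residual-variance scale of fold changes is
a calibration choice (no such scale is printed in the source study), set so
a few percent of probes reach q < 0.05 at n = 55.

Out of scope: bead-level array noise, probe cross-hybridization,
EBV-transformation effects, genotype data.

## Known limitations

- Full ML on 17 families has a small-sample downward bias in ĥ² of roughly
  0.03–0.05 (REML would halve it; the estimator here is pinned to ML). The
  acceptance targets absorb this inside their ±0.05 tolerance: measured
  means are ≈0.56 at truth 0.60 and ≈0.70 at truth 0.73 over 200
  replicates. The rank inverse-normal transform contributes ≈0.01 of the
  bias.
- The FC–SDR association test is slightly anti-conservative at n = 55
  (measured type-I ≈ 0.06 at nominal 0.05 with iid traits, and higher when
  the SDR itself is strongly heritable) — inherent to the ML LRT at this
  sample size, not an implementation artifact.
- The mean-FC test treats probes independently; no probe-level variance
  moderation (e.g. empirical Bayes shrinkage) is applied.
- SDR as an OLS slope ignores curvature of the dose–response; it is kept
  because it is the summary the analysis chain is defined on.
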