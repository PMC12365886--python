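# Methods

## Optical gap extraction and confinement sizing

The Tauc treatment assumes the absorption edge of an ultrasmall (< 5 nm)
gold colloid behaves like a direct-allowed semiconductor edge:
(αhν)^(1/n) = A·(hν − E_g) with Tauc exponent n = 1/2. Photon energies are
computed as E = hc/λ with hc = 1239.8420 eV·nm (CODATA). Absorbance is used
directly in place of the absorption coefficient α: the unknown path-length
and concentration factor rescales the Tauc ordinate multiplicatively and
leaves the x-intercept — the only quantity carried forward — unchanged
(asserted to 1e-9 eV in the tests).

**Linear-region selection.** A manual energy window is first-class and
recommended for reproducible reports. The automatic strategy fits ordinary
least squares on every contiguous window that

1. lies on the high-energy side of the edge inflection (first point whose
   smoothed gradient reaches 95% of the maximum),
2. lies above the localized surface-plasmon band, when one is detected: the
   most prominent absorbance peak is located in wavelength space and the
   window must sit at least 4 half-prominence half-widths above its centre
   (a Gaussian band has decayed to a negligible fraction of its height
   there),
3. spans at least 0.3 eV (configurable) and 5 points, has positive slope,
   and extrapolates to an intercept below the window,

and returns the window maximising r². Constraint 2 matters: plasmon
absorption is not part of the Tauc edge, and windows dipping into its
high-energy tail systematically drag the extrapolated intercept low. On
synthetic spectra with the default plasmon and 0.5% proportional noise,
adding the exclusion step reduced the mean absolute gap-recovery error from
≈ 0.025 eV to ≈ 0.013–0.017 eV over repeated 50-spectrum batches (the
round-trip test asserts < 0.02 eV). The OLS fit itself is the estimator; a
positive slope is required, otherwise a no-rising-edge error is raised.

**Size law.** R = (A_s/(E_g − E_g,bulk))^(1/n_s), with E_g,bulk = 0 for
gold (bulk gold is a metal), A_s ∈ 4.5–6.0 and n_s ∈ 1.3–1.5 empirically.
Defaults A_s = 5.0 and n_s = 1.4 sit mid-range and reproduce the reference
radii for gaps of 1.97 eV (R = 1.945 nm) and 1.92 eV (R = 1.981 nm); both
are configurable. The treatment is only meaningful in the confinement
regime, so results carry an applicability flag that goes false at diameters
≥ 5 nm.

**Report rounding.** Radii and diameters are kept at full precision
internally and truncated (not round-half) to two decimals in report tables:
the reference presentation pairs R = 1.94 nm with d = 3.89 nm, which is
mutually consistent only if the radius was truncated (1.9450 → 1.94) since
half-rounding 1.9450 gives 1.95 while the doubled value 3.8901 gives 3.89.
`TaucResult.rounded()` and the report scripts apply this convention;
nothing downstream consumes rounded values.

## Viability statistics

Absorbances are normalised as viability% = 100·A/mean(A_control); blank
subtraction is available but off by default. The pipeline then runs, in
order:

1. **Shapiro–Wilk** per group (scipy's Royston implementation; a group with
   fewer than 3 distinct values has no defined W and is flagged non-normal
   with a note) and **Levene's test** with mean centring (classic Levene,
   not Brown–Forsythe). If every group has zero spread the Levene statistic
   is reported as 0 with p = 1.
2. **One-way fixed-effects ANOVA** from explicit sums of squares, with
   partial η² = SSB/(SSB + SSW) (= SSB/SST in the one-way layout, an
   identity asserted to 1e-12). Zero within-group variance with unequal
   means reports F = +∞ with a warning rather than failing.
   **Kruskal–Wallis** (tie-corrected, χ² reference) is always computed and
   is marked as a *validation* run whenever any group failed normality —
   the ANOVA is never replaced, mirroring how such plates are analysed in
   practice. For small samples `kruskal_exact` enumerates every distinct
   assignment of the pooled observations to the group sizes and reports the
   exact permutation p (midranks throughout, so ties are handled
   identically in the observed and permuted statistics).
3. **Dunnett** many-to-one comparisons. The treatment-vs-control t
   statistics share the control mean and the pooled error, giving a
   multivariate t with factor correlation ρ_ij = λ_iλ_j,
   λ_j = √(n_j/(n_j + n_0)) (ρ = ½ balanced). The two-sided adjusted
   p-value 1 − P(max_j |T_j| ≤ |t_i|) is evaluated by deterministic
   Gauss–Hermite × Gauss–Legendre quadrature (64 × 96 nodes, accurate to
   ~1e-12; scipy's implementation uses randomised QMC, which is stochastic
   at the 1e-5 level and is used only as a cross-check in the tests). With
   a single treatment the procedure reduces exactly to the pooled
   two-sample t-test. **Tukey HSD** uses the studentized-range distribution
   with the Tukey–Kramer standard error. Adjusted p-values are floored at
   the unadjusted contrast p.
4. **Hedges' g** with the common small-sample correction
   J = 1 − 3/(4N − 9) and the df-weighted pooled SD. Zero pooled variance
   with unequal means is reported as undefined rather than infinite.

## Dose–response

V(c) = bottom + (top − bottom)/(1 + (c/IC₅₀)^h). Viability is
control-normalised, so top/bottom default to 100/0 and are fixed; freeing
them turns the model into the full 4-parameter logistic. The fit runs in
log₁₀ IC₅₀ space (initial value: geometric mean of the tested
concentrations; initial h = 1; h bounded to (1e-3, 50)) via
`scipy.optimize.curve_fit`. The IC₅₀ standard error is the delta-method
transform of the log-scale covariance, or optionally the SD of a seeded
bootstrap over replicates within each concentration. r² is computed on the
fitted points. Fits are flagged non-informative when h collapses to a
bound, the IC₅₀ lands far outside the tested range, or viability rises
with dose (Spearman ρ > 0.5) — an inhibitory Hill curve cannot describe
such data.

## Descriptors and drug-likeness

RDKit supplies the standard descriptors: Ertl fragment-contribution TPSA,
molecular weight, O–H/N–H donor and N+O acceptor counts (the rule-of-five
convention, which makes HBA equal the polar-atom count by construction),
rotatable bonds, Fsp3 and Wildman–Crippen logP (WLOGP). The Moriguchi
regression (MLOGP) is implemented here from its 13 structural descriptors
(carbon/halogen count, N+O count, N/O proximity with amide correction,
unsaturated bonds, intramolecular H-bond, aromatic polar substituents,
amphoteric motifs, hydrocarbon indicator, non-benzenoid rings, quaternary
N, nitro, thiocyanate, β-lactam; intercept −1.014); benzene evaluates to
2.28, matching the regression's own calculated value. The proximity,
substituent and H-bond terms use SMARTS-based detection that covers common
motifs rather than every literature edge case; for Lipinski gating, what
matters is the MLOGP > 4.15 arm, and the approximations are far from that
boundary for molecules like the diimide-diacid (MLOGP ≈ 0.6).

Lipinski violations are counted over {MW > 500, HBD > 5, HBA > 10,
MLOGP > 4.15} — the lipophilicity arm follows the convention of the common
web profilers rather than the original logP > 5, and is configurable in
the thresholds table. BOILED-Egg classification tests the (TPSA, WLOGP)
point against two axis-aligned ellipses reconstructed from the published
boundary extents of the model (white/absorption: TPSA ≤ 142, WLOGP
−2.18–6.82; yolk/BBB: TPSA ≤ 79.4, WLOGP 0.4–6.0); the exact fitted
ellipse coefficients are not republished with the model, so the shipped
ellipses are a faithful parameterisation of its stated boundaries, kept as
versioned constants. The radar flags use the published drug-like ranges:
logP −0.7–5.0 (WLOGP is used as the lipophilicity estimate), MW 150–500,
TPSA 20–130, ESOL log S −6–0 (the Delaney regression, computed here, is
the solubility proxy), Fsp3 ≥ 0.25, rotatable bonds ≤ 9.

The oDIDA structure is encoded from its systematic name,
N,N′-(1,2-phenylene)bis(phthalimide-5-carboxylic acid); the tests assert
the molecular formula C24H12N2O8 before any descriptor value.

## Synthetic data

The generators emulate the statistical structure of the study's
unpublished raw data, not its instrument physics:

- **Spectra**: absorbance = edge + plasmon + noise on a 350–800 nm grid
  (451 points). The edge inverts the Tauc relation,
  α = √(B(E − E_g))/E above the gap and 0 below (B = 8 by default, which
  puts the edge absorbance near 1 at the UV end, a typical measured
  scale); the plasmon is a Gaussian in wavelength (centre 520 nm, SD
  30 nm ≈ 70 nm FWHM, amplitude 0.30 — a clearly visible band as in
  measured colloid spectra); noise is i.i.d. Gaussian with SD 0.5% of the
  peak. Not emulated: Mie scattering, interband background curvature,
  baseline drift, stray light. Passing round-trip tests therefore shows
  the estimator handles a plasmon-obscured edge with realistic noise, not
  every artefact of a real spectrophotometer.
- **Plates**: i.i.d. normal replicates (default n = 9, SD 3%) around group
  means along the control/10/25/50/75/100 µM ladder (six groups — five
  between-group degrees of freedom, the design of the study). No
  plate-edge, batch or heteroscedastic effects; the type-I calibration
  result is exact-model calibration, not robustness.
- **Dose–response**: Gaussian noise around the Hill curve at the five
  tested concentrations.

All generators are pure functions of their spec including the seed;
rerunning with the same spec is bit-identical.

## Problem sizes and numerical choices

The statistical property checks use 50 spectra for the band-gap round
trip, 2000 plates for type-I calibration, 200 fits for IC₅₀
recovery/coverage and exhaustive enumeration up to 8 observations for the
exact Kruskal–Wallis — sizes at which the Monte-Carlo standard errors are
comfortably below the asserted margins while the whole suite runs in well
under a minute per property. Dunnett quadrature nodes (64 Hermite × 96
Legendre over the effective χ support) were chosen so the k = 2 reduction
to the t-test holds to ~1e-12, an order of magnitude beyond the 1e-6 the
tests assert. Ties in the exact Kruskal–Wallis are compared with a 1e-12
slack so permuted statistics equal to the observed one count as at least
as extreme.

## Known limitations

- The auto-window is tuned for edge-plus-single-band spectra; spectra with
  multiple overlapping bands or strong scattering backgrounds need a
  manual window.
- The size law's empirical constants (A_s, n_s) are degenerate over a
  range of values consistent with any single gap; sizing accuracy is
  limited by that empirical calibration, not by the fit.
- The Moriguchi implementation approximates the proximity/substituent
  bookkeeping for exotic functional groups; MLOGP values within ~0.2 of
  the 4.15 Lipinski boundary should not be trusted for gating.
- Dunnett assumes homoscedastic groups (pooled error); no
  Games–Howell-style fallback is provided.
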