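# Methods

This note documents the models, the numerical choices, and the scope of the
synthetic-data generators — what a passing test suite does and does not say
about real data.

## Contact mechanics

**Units.** All force-curve work is done in nm, nN and kPa (1 N/m × 1 nm =
1 nN; 1 kPa = 10⁻⁶ nN/nm²). Compression uses s, μN, μm and kPa
(1 μN/μm² = 1 MPa). Conversions happen only at the I/O boundary.

**Contact detection.** The baseline is a line fitted to the first half of
the approach segment, robustified by one reweighting pass that drops
residuals beyond 3 scaled MADs. Contact is the first sustained exceedance of
5 × the residual MAD (plus a tiny absolute floor so noiseless curves are
handled), walked back to the ~1-MAD crossing. The detected index is
therefore quantised to the piezo sampling grid; downstream fits must either
tolerate an O(one-sample) offset or refine it.

**Hertz sphere fit.** F = (4/3)·(E/(1−ν²))·√R·δ^{3/2} is linear in E, so
the core fit is a projection onto δ^{3/2}. By default a contact-offset
nuisance parameter δ₀ (bounded to ±10% of the depth range) is refined
jointly by nonlinear least squares, absorbing the grid quantisation of the
detected contact; `refine_contact=False` gives the pure projection, which
the scale-invariance tests use. E is reported at the stated sample Poisson
ratio (0.5 for hydrated tissue).

**Oliver–Pharr.** The unloading power law P = α(h−h_f)^m is fitted (in
log-α parameterisation, bounds h_f < min window depth, m ∈ [0.5, 5]) to the
points with P ∈ [0.75, 0.95]·P_max — the upper part of unloading with the
very top excluded to avoid contact/adhesion artefacts. ε = 0.75 and β = 1
(canonical values; both exposed as arguments). The area function is a
geometric blunted cone: a spherical cap of the tip radius (default 8.5 nm,
the midpoint of a 7–10 nm tip) joining the cone tangentially at depth
R_t(1−sinθ). The tip is treated as rigid, so M = √π·S/(2β√A) is the
plane-strain modulus E/(1−ν²) with no tip-compliance correction. Fits with
m outside [1, 3] are flagged, not rejected. Expected systematic error of
the whole chain on an ideal Sneddon cone is ≈ +2% from the ε convention
minus a blunting term that shrinks with depth; the round-trip tolerance of
5% reflects this, and the default synthetic depth (≳600 nm) keeps the
blunting term small.

**Two-plate compression.** The platen travel δ is split equally between the
two plate contacts, giving F = (4/3)·(E/(1−ν²))·√R·(δ/2)^{3/2} per radius.
E is inverted point-wise inside the 10–20% engineering-strain window (the
toe region below is excluded by construction) and averaged over the window,
then over the horizontal- and vertical-radius estimates; a single
3/2-power-law fit over the window is available as `method="powerlaw"` and
agrees with point-wise averaging to well under 1% on clean traces. Cycle
segmentation is driven by displacement increments and levels only, so it is
invariant to time-axis shifts; the fifth (stabilised) cycle is analysed and
the cycle-4→5 peak-force drift is exposed as a preconditioning diagnostic.
The contact-radius validity a ≪ R is checked and warned at a/R > 0.5, not
enforced. The exact "modified" Hertz variant used with this instrument class
is not published; the equal-split two-plate model above is this package's
documented choice, validated internally by round trip rather than against
external absolute values.

## Fibril morphometry

**D-period.** The long-axis profile is linearly detrended and its unbiased
normalised autocorrelation computed. Candidate peaks are searched only after
the zero-lag main lobe has decayed below 0.2 — a smooth banded profile keeps
r(l) high at small lags, and noise wiggles there would otherwise masquerade
as short periods. A peak is significant if it exceeds 3 × a noise floor
estimated from the *first differences* of the autocorrelation beyond three
candidate periods (scaled MAD/√2). A raw far-lag MAD would reject a clean
periodic profile, whose autocorrelation stays large at all lags; the
first-difference floor measures only the high-frequency noise level, which
is the quantity of interest, while still rejecting flat noisy profiles. The
returned period regresses the parabolic-refined peak positions at integer
multiples of the first peak on the multiple index, which keeps the error
below half a pixel at SNR ≥ 5 (verified to ~0.3 nm worst-case over 50 seeds
at SNR 5 with 1 nm pixels).

**Diameter.** Per transverse section, diameter = maximum height minus the
median of the flanking quarter of samples on each side (local background).
Height, not apparent width, is used — the AFM convention that avoids lateral
tip convolution. The median over sections is returned. Sections whose flanks
contain fewer than 2 samples per side are rejected.

**Shortest axis.** Connected components (8-connectivity) are reduced to
convex hulls and the rotating-calipers minimum width computed over hull
edges; one pixel is added to account for the pixel footprint (centres span
n−1 pixels of an n-pixel-wide object).

**Distributions.** Histograms share bins anchored at 0 (default width 5 nm);
skewness is the adjusted Fisher–Pearson g1; exactly two groups trigger a
two-sided Mann–Whitney comparison.

## Biochemistry

Collagen from hydroxyproline uses M_hyp = 131.13 g/mol (free hydroxyproline,
matching assay standards; configurable), 300 residues and 300 kDa per triple
helix. Cross-link densities are per mole of collagen; ratios with zero
denominators are returned as NaN and listed as undefined rather than raised.
Solubility fractions are percentages of the summed hydroxyproline and always
total 100. ΔCt subtracts the arithmetic mean of housekeeping Cts (equivalent
to a geometric mean on the expression scale); the ΔΔCt baseline is a named
sample or the mean ΔCt of a designated control group; group summaries are
geometric means over 2^(−ΔΔCt) values.

## Statistics

Mann–Whitney is exact for combined n ≤ 20 without ties, otherwise the normal
approximation with mid-ranks and tie correction. Identical samples
short-circuit to statistic 0, p = 1 (the generic formulas are 0/0 there).
Log transforms are base-10; test statistics are invariant to the base.
Holm–Šidák is the step-down 1−(1−p)^(m−i+1) with running-maximum
monotonicity (via statsmodels).

The independent-groups Dunnett test uses scipy's multivariate-t
implementation; with exactly one comparison the family collapses to a single
pooled-variance t and the exact univariate p is used. The repeated-measures
design computes the two-way (blocks × conditions) cell-mean decomposition,
assumes sphericity (the design is a randomised block), and forms
vs-control contrasts on the error mean square with df = (k−1)(n−1); the
family-wise adjustment is the max-|T| distribution of equicorrelated
(ρ = ½) t statistics sharing one variance estimate, evaluated by seeded
Monte Carlo with 10⁵ draws (fixed internal seed, so p-values are
deterministic; resolution ~0.003). Dunn's post-hoc uses the rank z statistic
with tie correction and Bonferroni adjustment across the vs-control family.

Missing-data correlation estimates the multivariate-normal mean and
covariance by EM, processing rows grouped by missingness pattern
(conditional means and covariances per pattern, so the E-step is
vectorised). Convergence is |Δ log-likelihood| < 10⁻⁸·(1+|ℓ|), at most 500
iterations, with an eigenvalue floor keeping Σ positive definite. On
complete data the first iteration is already the ML solution, so the
correlations equal Pearson's. This is the likelihood-based analogue of the
REML missing-data handling in common statistics packages; for
covariance-only estimation at cohort-scale n the ML/REML distinction is
negligible. p-values use the t approximation with the pairwise observed
count as effective n — the convention for the alternative (total-n) is not
externally fixed, so the conservative pairwise choice is made and reported.

The 4PL dose-response fit works on log₁₀ dose with free top, bottom, hill
(bounded [0.05, 10]) and log-IC50, initialised from the half-maximum
crossing; flat responses raise instead of fitting.

## Synthetic-data generators: what they emulate

Every generator draws from the forward model its analysis counterpart
inverts, so noiseless outputs are exactly invertible up to fit tolerance;
ground truth travels in a `meta["truth"]` sidecar and the seed is echoed in
the metadata. Deliberate idealisations: no instrument hysteresis, thermal
drift, adhesion, or viscoelasticity in force curves; displacement in
compression traces is noiseless (instrument-controlled) with noise on force
only; fibril topographies are straight ridges with Gaussian cross-section
and raised-sinusoid (optionally smoothed-square gap/overlap) banding, not
traced real fibrils. Passing round trips therefore demonstrate correctness
of the inversions under their own assumptions, not robustness to real
instrument artefacts.

The indentation generator solves the cantilever force balance
k(z−z_c−δ) = F(δ) per piezo position, places contact at mid-range (so the
contact detector's first-half baseline convention holds), and generates
unloading as P = α(h−h_f)^m with α continuous at peak load and m defaulting
to the elastic exponent. The compression generator uses an effective radius
√R_eff = 2/(1/√R_h + 1/√R_v) so that the analysis's two-axis average
recovers E_true exactly (with equal radii this is plain two-plate Hertz),
and a smoothstep toe below 8% strain that leaves the 10–20% analysis window
untouched.

Cohorts are drawn per group from a multivariate normal on the transformed
scale (natural log for stiffness, cross-link densities, fibril diameter and
swelling ratio — matching the log-scale analyses and giving the
right-skewed diameter distributions; linear for collagen concentration)
with correlations imposed by Cholesky factorisation. The default contrast:
control/case geometric-mean stiffness 2/5 kPa, immature cross-links 0.6/1.2
and mature 0.25/0.55 per collagen, diameters 97/80 nm (an 18% reduction),
swelling 2.5/1.9, collagen 75/75 μg/mg; within-group log-scale correlation
0.72 between stiffness and mature cross-links, 0.35 to immature, 0.5
between the cross-link pools. Inter-donor variance components are not
published for these measurements, so the spreads (σ_log 0.15–0.35, collagen
SD 15) are this package's realistic choices, documented here and not
calibrated further. Note that with group effects present the *pooled*
stiffness–cross-link correlation exceeds the within-group target (e.g.
r ≈ 0.9 at the defaults); the null-contrast configuration recovers the
generative value directly. Missingness is MCAR per cell (no mechanism is
published), never touching identifiers.

Dose-response tables support additive noise (percent-activity units) and
multiplicative noise (assay CV). The replicated recovery analyses use a 2%
CV with 10 log-spaced doses in triplicate — a typical enzymatic screening
design; with a single well per dose the IC50 sampling spread alone exceeds
a 10% worst-case bound over 100 seeds, regardless of estimator.

## Problem sizes

Defaults are sized for complete desk-scale runs: indentation curves 600
samples, topographies ~2010 × 360 px at 1 nm, compression traces 1700
samples (0.1 s sampling over five 34 s cycles), cohorts 15 + 17 donors.
Simulation-based checks use 100 seeds (round-trip and power claims), 200
seeds (EM recovery, Mann–Whitney power) or 2000 replicates (type-I error and
family-wise error calibration); the full suite runs in a few minutes on one
core.

## Known limitations

- No adhesion (JKR/DMT) or viscoelastic models; unloading is treated as
  purely elastic.
- No tip-deconvolution of lateral widths and no automated fibril tracing;
  profiles and sections are caller-supplied polylines.
- The two-plate Hertz inversion assumes small contact radius; at 25%
  engineering strain this is an extrapolation shared with the protocol it
  models (warned at a/R > 0.5).
- The EM correlation assumes joint normality on the analysis scale and
  missingness at random.
- RM-Dunnett p-values are Monte-Carlo estimates with ~0.003 resolution.
- No proprietary instrument binary formats; plain text (and TIFF for
  topographies) only.
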