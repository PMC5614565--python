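# Methods

## Binding models

All mechanisms describe the WAVE regulatory complex (WRC, the receptor W,
total W_tot) binding Rac1 presented as a GST fusion (ligand R, totals
counted per Rac1 monomer). Concentrations and dissociation constants are
in μM throughout. Ligand depletion is always accounted for: the solvers
work with total concentrations and conservation laws, never the
excess-ligand approximation, because the pull-down titrations cross the
regime where W_tot (0.1 μM) is comparable to both K_Ds and ligand totals.

For the two-site mechanisms the solver uses the binding polynomial
Q(r) = 1 + c₁r + c₂r², where r is free Rac1:

- sequential: c₁ = 1/K_D,D, c₂ = 1/(K_D,D·K_D,A(D));
- cyclic: c₁ = 1/K_D,D + 1/K_D,A, c₂ = α/(K_D,D·K_D,A).

Free receptor is W_tot/Q(r), and ligand conservation
r + W_tot·(c₁r + 2c₂r²)/Q(r) = R_tot is strictly increasing in r, so the
root is unique and bracketed in [0, R_tot]. The GST-dimer mechanism
(dimer total R_tot/2) is the mirror image with free WRC as the 1-D
unknown. Roots are found by Brent's method at ~4·ε relative tolerance for
single-state solves, and by fixed-count vectorized bisection (64
halvings, which exhausts double precision) for whole-titration
predictions inside fits. Conservation residuals are below 10⁻⁹ relative
across totals of 10⁻⁴–10³ μM and constants of 10⁻³–10³ μM (property
tested).

Cooperativity parameterization: α multiplies the doubly bound species,
[WR_DA] = α[W]r²/(K_D,D·K_D,A), so K_D,A(D) = K_D,A/α and the
thermodynamic cycle K_D,D·K_D,A(D) = K_D,A·K_D,D(A) holds by
construction; α > 1 is positive cooperativity. Constants must be
positive and finite — 0 and ∞ are rejected, and limiting behavior
(e.g. a dead second site) is exercised numerically at 10¹² μM in tests
only.

### Identifiability

The pull-down observable depends on the cyclic model's three parameters
only through (c₁, c₂): a single isotherm cannot separate K_D,D, K_D,A,
and α. The cyclic fit is therefore provided but expected to sit on a
ridge; `fit_report` flags a parameter as non-identifiable when its
Monte-Carlo draw histogram spans more than two decades. Recovery
guarantees are stated for the single-site, sequential, and GST-dimer
mechanisms, which are identifiable from one isotherm.

## Isotherm fitting and model discrimination

Unweighted least squares on fraction unbound: replicate experiments are
pooled directly into one isotherm, each point with equal weight, because
the observable is already normalized per reaction. Parameters are fit as
log₁₀K with bounds 10⁻⁴–10⁴ μM (the constants of interest span
0.033–11.52 μM); optimization is `scipy.optimize.least_squares` (TRF)
from a deterministic multi-start grid, default log₁₀K ∈
{−2, −1, 0, 1, 2} per parameter, ties broken by lowest SSR then smallest
parameter vector. A fit needs at least max(6, p + 2) points.

Nested mechanisms are compared with the extra-sum-of-squares F-test;
when the complex model fails to reduce the SSR, F is clamped to 0 and
p = 1. One caveat is inherent to mechanism nesting: the simpler
mechanism sits on the *boundary* of the richer one's parameter space
(a dead second site is K_D,A(D) → ∞), so under the null roughly half
or more of the fits land on the clamp, p-values pile up at 1 rather
than being uniform, and the test is conservative — in null simulations
at gel-level noise its false-positive rate at the 0.05 threshold is
well below 0.05 (around 0.005–0.01; noise censoring by the [0, 1.2]
observable clip on the saturated tail adds to this). The practical
consequence is benign — the test under-claims second sites, never
over-claims them — and its power on genuine two-site data at the same
noise level is essentially 100%.

Uncertainty uses a residual-shuffle Monte Carlo: residuals are permuted
across points without replacement, added back to the fitted curve, and
the model refit from the converged solution; 5,000 iterations by
default, fully reproducible from the seed. Shuffling (not bootstrap
resampling) is the default because it preserves the exact residual
multiset; a bootstrap variant is available via `method="bootstrap"`.
Refits that fail are dropped and counted, with a warning flag above 20%.

## Species distributions and specific activity

Solution actin-assembly assays have no avidity surface, so species
concentrations across a Rac1 titration are computed under the cyclic
model with α = 1 (independent sites; WR_DA = W_tot·p_D·p_A with
p = r/(r + K_D) at the solved free r). Default constants are the
intact-site values K_D,D = 0.265 μM and K_D,A = 11.52 μM at
W_tot = 0.1 μM. The activity model is a free-intercept OLS line of
maximum assembly rate (nM/s) against the chosen species concentration
(nM): the intercept is left free because Arp2/3 plus WRC alone assembles
actin at a small nonzero baseline rate. Against WR_DA this line is the
bivalent-activation prediction; against total bound WRC it is visibly
curved (r² contrast > 0.1 on the synthetic fixture).

The synthetic activity fixture titrates Rac1 over 0–1.5 μM (8 points)
with specific activity 0.22 nM·s⁻¹/nM and baseline 0.3 nM/s, spanning
rates of ~0.3–1.5 nM/s; with 0.05 nM/s Gaussian rate noise this sits in
the r² ≈ 0.98–0.99 regime.

## Pyrene kinetics

Fluorescence is converted to polymer by
P(t) = (F − F₀)/(F∞ − F₀)·(A_tot − A_cc), with F₀ and F∞ the means of
the first and last 5% of points (trimmed tails are robust to single-point
spikes) and A_cc the critical concentration, default 0.1 μM and
configurable since the conversion constant depends on assay conditions.
A trace whose rise is under five baseline-noise standard deviations is
rejected as unsaturated unless a plateau is supplied.

The maximum assembly rate is the largest OLS slope over all contiguous
windows (default width 5% of the trace, minimum 11 points, odd), times
1000 to nM/s. Windowed OLS is the entire smoother — no splines — so the
estimator is auditable: for a smooth trace the window-averaging bias is
bounded by (kΔt)²·|P‴|/24, second order in the window's time width, and
the estimate is affine-invariant in fluorescence. For a logistic trace
with amplitude ΔP and time constant τ the true maximum slope is ΔP/(4τ),
which the estimator matches within that bound (tested, including the
second-order convergence under grid refinement).

## MSSV stoichiometry

The spectral step of multi-signal sedimentation velocity: at each s, the
absorbance (490 nm) and interference densities are an invertible 2×2
linear map of the component molar densities, with defaults
ε₄₉₀ = 32,310.8 AU·M⁻¹cm⁻¹ (EGFP-Rac1, calibrated value reflecting
incomplete EGFP maturation), fringe increments 141,801 (EGFP-Rac1) and
904,251 (WRC) fringes·M⁻¹cm⁻¹, and a 1.2 cm optical path (standard
dual-sector centerpiece). The system's condition number must be below
10⁶. Negative decomposed concentrations are retained and flagged — they
diagnose increment misspecification — with optional flooring at
integration time only. Peak integrals are trapezoidal; the molar ratio
is Rac/WRC, and the signal-average sedimentation coefficient is the
interference-weighted mean of s over the range. The ratio is undefined
(an error) when the WRC integral is non-positive or negligible
(< 10⁻⁹×) next to the Rac integral. The hydrodynamic c(s) inversion
that produces the signal distributions is upstream and out of scope.

## Synthetic data: what it does and does not emulate

Generators mirror the experimental designs — a 24-point geometric
titration of 0.01–140 μM GST-Rac1 against 0.1 μM WRC; logistic pyrene
traces at 4 μM actin (5% labeled); Gaussian c_k(s) peaks with free
EGFP-Rac1 at 3.5 S and the WRC near 10.5 S — with additive Gaussian
noise on the observable (gel densitometry and fringe noise are
approximately additive at these signal levels), isotherm readings
clipped to [0, 1.2]. Every generator is a pure function of its
arguments including the seed, and embeds its generating truth in the
output provenance.

They do not emulate: systematic gel-densitometry nonlinearity or
between-experiment offsets in pooled isotherms; polymerization lag
phases, photobleaching, or detector drift in pyrene traces; regularized
c(s) peak shapes, baseline artifacts, or s-dependent noise in AUC data.
Passing recovery tests therefore demonstrate the estimators are correct
under the stated noise model, not that real-data systematics are
handled.

## Problem sizes

Defaults used by the test suite and the acceptance script: 24-point
isotherms; 200 replicates per operating-characteristic simulation;
Monte-Carlo runs at 500 iterations where many are needed (the API
default stays 5,000); 4,800-sample pyrene traces; 621-point s grids.

## Known limitations

- Kinetic (time-dependent) binding, bead-surface geometry, and avidity
  beyond the explicit GST-dimer mechanism are not modeled.
- The fraction-space, unweighted objective is a choice; fitting pooled
  replicates with per-experiment weights could differ when replicate
  noise is heterogeneous.
- The cyclic model's non-identifiability from single isotherms is
  inherent to the observable, not a solver limitation.
- Negative observed fractions are clipped at generation, which slightly
  censors the noise distribution for very weak binders near f = 1.2 or
  strong binders near f = 0.
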