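# wrcbind

Quantitative analysis of how the Rho-family GTPase **Rac1 activates the
WAVE regulatory complex (WRC)** through two binding sites of very
different affinity. The WRC carries a high-affinity "D Site" and a
~40-fold weaker "A Site" on its Sra1 subunit, and measurable actin
assembly requires both sites to be engaged — a bivalent activation
mechanism. `wrcbind` is for biophysicists who run equilibrium pull-down
titrations, pyrene-actin assembly assays, and multi-signal
sedimentation-velocity AUC, and want the full numerical chain from raw
observables to dissociation constants, stoichiometries, and specific
activities — with honest model discrimination and uncertainty.

## What it computes

**Equilibrium binding (`wrcbind.equilibria`, `wrcbind.epd_fit`).** Exact
mass-action solvers with ligand depletion for four mechanisms of WRC (W)
binding GST-Rac1 (R):

- single site: W + R ⇌ WR, constant *K*<sub>D,D</sub>;
- sequential two-site: W + R ⇌ WR<sub>D</sub> (*K*<sub>D,D</sub>),
  WR<sub>D</sub> + R ⇌ WR<sub>DA</sub> (*K*<sub>D,A(D)</sub>);
- cyclic two-site with cooperativity α, *K*<sub>D,A(D)</sub> =
  *K*<sub>D,A</sub>/α, detailed balance enforced by construction;
- GST-dimer avidity: a GST-Rac1 dimer G₂ binding one WRC
  (*K*<sub>D,A</sub>) then a second (*K*<sub>D,A′</sub>).

Each reduces to a bracketed, monotone 1-D conservation equation solved by
Brent/bisection, so convergence is guaranteed. The equilibrium pull-down
observable is the fraction of WRC left unbound,
*f* = [W]<sub>free</sub>/W<sub>tot</sub>. Isotherms are fit by
least squares in log₁₀*K* space from a multi-start grid, nested
mechanisms are compared with the extra-sum-of-squares F-test,

F = ((SSR₁ − SSR₂)/(p₂ − p₁)) / (SSR₂/(n − p₂)),

and parameter uncertainty comes from a residual-shuffle Monte Carlo
(5,000 permute-and-refit iterations by default).

**Bivalent activation (`wrcbind.species_activity`).** Species
concentrations W, WR<sub>D</sub>, WR<sub>A</sub>, WR<sub>DA</sub> across a
Rac1 titration under the cyclic model with α = 1, and the ordinary
least-squares line of maximum actin assembly rate against a chosen
species. The slope against WR<sub>DA</sub> is the specific activity
(nM actin · s⁻¹ per nM of doubly bound WRC).

**Rate extraction (`wrcbind.pyrene_kinetics`).** Pyrene fluorescence →
polymerized actin via baseline/plateau normalization, then the maximum
windowed OLS slope in nM/s.

**Stoichiometry (`wrcbind.mssv_stoich`).** Two-signal (absorbance-490 +
interference) c<sub>k</sub>(s) decomposition with calibrated molar signal
increments, peak integration, Rac1:WRC molar ratios, and
interference-weighted average sedimentation coefficients.

**Generators (`wrcbind.synthetic_data`).** Seedable synthetic versions of
all three input kinds with the generating truth embedded in provenance.

## Worked example

```python
import numpy as np
from wrcbind import MechanismSpec, fit_isotherm, f_test, monte_carlo_errors
from wrcbind.synthetic_data import NoiseSpec, simulate_isotherm

# a 24-point pull-down titration (0.01-140 uM GST-Rac1 vs 0.1 uM WRC)
# generated under the sequential two-site mechanism with gel-level noise
truth = MechanismSpec.sequential_two_site(kd_d=0.169, kd_ad=0.262)
iso = simulate_isotherm(truth, noise=NoiseSpec(sd=0.01, seed=7))

one = fit_isotherm(iso, "single_site")
two = fit_isotherm(iso, "sequential_two_site")
cmp_ = f_test(one, two)
mc = monte_carlo_errors(two, iso, n_iter=500, seed=7)
for name in two.param_names:
    print(f"{name} = {two.params[name]:.3f} +/- {mc.standard_errors[name]:.3f} uM")
print(f"two-site vs single-site: F = {cmp_.f_statistic:.1f}, p = {cmp_.p_value:.2e}")
```

prints

```
K_D_D = 0.165 +/- 0.003 uM
K_D_A_D = 0.279 +/- 0.022 uM
two-site vs single-site: F = 813.3, p = 7.20e-19
```

i.e. the D-site constant is recovered near its generating value of
0.169 μM, the second-site constant near 0.262 μM, and the F-test rejects
the single-site description of two-site data decisively.

The same workflow is available from the shell:

```sh
wrcbind simulate-epd --model sequential_two_site \
    --param K_D_D=0.169 --param K_D_A_D=0.262 --noise-sd 0.01 --seed 7 --out iso.csv
wrcbind fit-epd --model sequential_two_site --isotherm iso.csv
wrcbind compare-models --isotherm iso.csv --models single_site,sequential_two_site
```

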