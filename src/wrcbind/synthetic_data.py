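"""Seedable generators for every input kind the analysis modules consume.

The study's raw numerical data (gel-densitometry isotherms, pyrene
fluorescence traces, sedimentation signal distributions) are not deposited
anywhere machine-readable, so these generators produce inputs with the
statistical structure the analyses assume: equilibrium pull-down isotherms
under any supported mechanism with additive Gaussian gel noise; logistic
pyrene traces with a known analytic maximum slope; and Gaussian c_k(s)
peaks synthesized through the calibrated signal increments.  Defaults
follow the experimental conditions: 0.1 uM WRC titrated with GST-Rac1 from
0.01 to 140 uM over 24 geometric points; 4 uM actin, 5% pyrene-labeled;
free EGFP-Rac1 sedimenting at 3.5 S and the WRC near 10.5 S.

Every generator is a pure function of its arguments including the seed, and
embeds its generating truth in the output provenance so downstream tests
can compare against it without re-deriving anything.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .epd_fit import MAX_OBSERVED_FRACTION, Isotherm
from .equilibria import MechanismSpec, predict_fraction_unbound
from .errors import ParameterDomainError
from .mssv_stoich import SignalDistributions, SignalIncrements
from .pyrene_kinetics import PyreneTrace

__all__ = [
    "NoiseSpec",
    "CkComponent",
    "make_titration",
    "simulate_isotherm",
    "simulate_pyrene",
    "simulate_ck",
    "DEFAULT_TITRATION_LOW",
    "DEFAULT_TITRATION_HIGH",
    "DEFAULT_TITRATION_N",
]

DEFAULT_TITRATION_LOW = 0.01  # uM GST-Rac1, lowest point used experimentally
DEFAULT_TITRATION_HIGH = 140.0  # uM, highest point
DEFAULT_TITRATION_N = 24
DEFAULT_RECEPTOR_TOTAL = 0.1  # uM WRC in every pull-down reaction

FREE_RAC_S = 3.5  # Svedberg, free EGFP-Rac1
FREE_WRC_S = 10.5  # Svedberg, ligand-free WRC


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise on the observable, with a mandatory seed."""

    sd: float
    seed: int
    kind: str = "gaussian"

    def __post_init__(self):
        if self.kind != "gaussian":
            raise ParameterDomainError(f"unsupported noise kind {self.kind!r}")
        if not (math.isfinite(self.sd) and self.sd >= 0):
            raise ParameterDomainError("noise sd must be finite and >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def make_titration(
    low: float = DEFAULT_TITRATION_LOW,
    high: float = DEFAULT_TITRATION_HIGH,
    n: int = DEFAULT_TITRATION_N,
    spacing: str = "geometric",
) -> np.ndarray:
    """Ligand totals (uM) for a titration, geometric by default."""
    if not (0 < low < high) or not (math.isfinite(low) and math.isfinite(high)):
        raise ParameterDomainError(f"need 0 < low < high, got low={low}, high={high}")
    if n < 2:
        raise ParameterDomainError("a titration needs at least 2 points")
    if spacing == "geometric":
        return np.geomspace(low, high, n)
    if spacing == "linear":
        return np.linspace(low, high, n)
    raise ParameterDomainError(f"unknown spacing {spacing!r}")


def simulate_isotherm(
    mechanism: MechanismSpec,
    receptor_total: float = DEFAULT_RECEPTOR_TOTAL,
    ligand_totals: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    label: str = "",
) -> Isotherm:
    """Equilibrium pull-down isotherm under a known mechanism.

    Noise-free model fractions plus additive Gaussian noise, clipped to
    [0, 1.2] (negative gel readings are not reported; mild overshoot above
    1 is).  The generating mechanism, noise level, seed, and true fractions
    are stored as JSON in the isotherm provenance.
    """
    if ligand_totals is None:
        ligand_totals = make_titration()
    ligand_totals = np.asarray(ligand_totals, dtype=float)
    truth = predict_fraction_unbound(mechanism, ligand_totals, receptor_total)
    observed = truth.copy()
    sd = 0.0
    seed = None
    if noise is not None and noise.sd > 0:
        sd = noise.sd
        seed = noise.seed
        observed = truth + noise.rng().normal(0.0, noise.sd, size=truth.shape)
    observed = np.clip(observed, 0.0, MAX_OBSERVED_FRACTION)
    provenance = json.dumps(
        {
            "generator": "simulate_isotherm",
            "mechanism_kind": mechanism.kind,
            "parameters": dict(mechanism.parameters),
            "receptor_total_uM": receptor_total,
            "noise_sd": sd,
            "seed": seed,
            "true_fraction_unbound": truth.tolist(),
        }
    )
    return Isotherm(
        ligand_total=ligand_totals,
        receptor_total=receptor_total,
        fraction_unbound=observed,
        label=label or f"synthetic-{mechanism.kind}",
        provenance=provenance,
    )


def simulate_pyrene(
    f0: float = 1.0,
    fmax: float = 10.0,
    t_half: float = 600.0,
    tau: float = 120.0,
    n: int = 1200,
    dt: float = 1.0,
    noise: NoiseSpec | None = None,
    actin_total: float = 4.0,
    pyrene_fraction: float = 0.05,
    critical_conc: float = 0.1,
    label: str = "",
) -> PyreneTrace:
    """Logistic pyrene fluorescence trace with a known analytic maximum slope.

    F(t) = f0 + (fmax - f0) / (1 + exp(-(t - t_half)/tau)); the true
    maximum fluorescence slope (fmax - f0)/(4 tau) and the corresponding
    polymer-space slope (actin_total - critical_conc)/(4 tau) are recorded
    in the trace provenance.
    """
    if not fmax > f0:
        raise ParameterDomainError("fmax must exceed f0")
    if tau <= 0 or dt <= 0:
        raise ParameterDomainError("tau and dt must be positive")
    t = np.arange(n, dtype=float) * dt
    f = f0 + (fmax - f0) / (1.0 + np.exp(-(t - t_half) / tau))
    sd = 0.0
    seed = None
    if noise is not None and noise.sd > 0:
        sd = noise.sd
        seed = noise.seed
        f = f + noise.rng().normal(0.0, noise.sd, size=f.shape)
    provenance = {
        "generator": "simulate_pyrene",
        "f0": f0,
        "fmax": fmax,
        "t_half": t_half,
        "tau": tau,
        "noise_sd": sd,
        "seed": seed,
        "true_max_fluor_slope_au_per_s": (fmax - f0) / (4.0 * tau),
        "true_max_rate_nM_per_s": (actin_total - critical_conc) / (4.0 * tau) * 1e3,
    }
    return PyreneTrace(
        time=t,
        fluorescence=f,
        actin_total=actin_total,
        pyrene_fraction=pyrene_fraction,
        critical_conc=critical_conc,
        label=label or "synthetic-logistic",
        provenance=provenance,
    )


@dataclass(frozen=True)
class CkComponent:
    """One Gaussian co-sedimenting species in a synthetic c_k(s) pair."""

    s0: float  # Svedberg, peak position
    width: float  # Svedberg, Gaussian sd
    rac_conc: float  # uM of EGFP-Rac1 in the species
    wrc_conc: float  # uM of WRC in the species

    def __post_init__(self):
        if self.width <= 0:
            raise ParameterDomainError("peak width must be positive")
        if self.rac_conc < 0 or self.wrc_conc < 0:
            raise ParameterDomainError("component concentrations must be >= 0")


def default_s_grid() -> np.ndarray:
    return np.linspace(0.5, 16.0, 621)


def simulate_ck(
    components: list[CkComponent],
    inc: SignalIncrements | None = None,
    s_grid: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> SignalDistributions:
    """Two-signal densities from Gaussian concentration peaks.

    Each component contributes a Gaussian molar concentration density; the
    absorbance and interference densities are synthesized through the
    signal increments, then Gaussian noise (in interference units; scaled
    to the absorbance channel by the increment ratio) is added.
    """
    inc = inc or SignalIncrements()
    if s_grid is None:
        s_grid = default_s_grid()
    s_grid = np.asarray(s_grid, dtype=float)
    if s_grid.ndim != 1 or s_grid.size < 2 or np.any(np.diff(s_grid) <= 0):
        raise ParameterDomainError("s grid must be 1-D and strictly increasing")
    c_rac = np.zeros_like(s_grid)
    c_wrc = np.zeros_like(s_grid)
    for comp in components:
        shape = np.exp(-0.5 * ((s_grid - comp.s0) / comp.width) ** 2) / (
            comp.width * math.sqrt(2.0 * math.pi)
        )
        c_rac += comp.rac_conc * 1e-6 * shape
        c_wrc += comp.wrc_conc * 1e-6 * shape
    l = inc.path_length
    absorbance = inc.epsilon_490 * l * c_rac
    interference = l * (inc.fringe_rac * c_rac + inc.fringe_wrc * c_wrc)
    if noise is not None and noise.sd > 0:
        rng = noise.rng()
        interference = interference + rng.normal(0.0, noise.sd, size=s_grid.shape)
        absorbance = absorbance + rng.normal(
            0.0, noise.sd * inc.epsilon_490 / inc.fringe_rac, size=s_grid.shape
        )
    return SignalDistributions(
        s_grid=s_grid,
        absorbance_density=absorbance,
        interference_density=interference,
    )
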