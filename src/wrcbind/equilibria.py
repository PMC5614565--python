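"""Mass-action equilibrium solvers for Rac1 binding to the WAVE regulatory complex.

The WRC (the receptor, symbol W) carries two Rac1-binding surfaces on its
Sra1 subunit: the high-affinity "D Site" (distant from the VCA pocket) and
the lower-affinity "A Site" (adjacent to it).  Equilibrium pull-down
titrations of WRC against GST-Rac1 are described by one of four mechanisms,
each solved here exactly, with ligand depletion (totals are conserved, free
concentrations are solved for — no excess-ligand approximation):

``single_site``
    W + R <-> WR with constant ``K_D_D``.  Closed-form quadratic.
``sequential_two_site``
    W + R <-> WR_D (``K_D_D``), WR_D + R <-> WR_DA (``K_D_A_D``).  The A
    site is only populated once the D site is occupied.
``cyclic_two_site``
    Both sites fill in either order: W + R <-> WR_D (``K_D_D``),
    W + R <-> WR_A (``K_D_A``), and the doubly bound complex WR_DA with
    cooperativity ``alpha`` such that K_D_A(D) = K_D_A / alpha.  Detailed
    balance around the cycle is enforced by construction: alpha multiplies
    the second binding step regardless of order.
``gst_dimer``
    Dimeric GST-Rac1 (G2, at half the Rac1 monomer total) binds one WRC
    (``K_D_A``) and then a second WRC cooperatively (``K_D_Aprime``):
    G2 + W <-> G2W, G2W + W <-> G2W2.  This is the bead-avidity mechanism
    needed when only the A site is functional.

All concentrations and dissociation constants are in uM.  Ligand totals are
stated per Rac1 monomer; for ``gst_dimer`` the dimer total is half the
monomer total.

Solvers reduce every mechanism to a bracketed, monotone one-dimensional
conservation equation (free ligand for the two-site mechanisms, free
receptor for the GST-dimer mechanism) solved by Brent's method, so there is
no initialization sensitivity.  ``predict_fraction_unbound`` provides a
vectorized bisection path over whole titrations for fitting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .errors import ParameterDomainError, UndefinedObservableError

__all__ = [
    "KINDS",
    "MechanismSpec",
    "MixtureSpec",
    "EquilibriumState",
    "solve_single_site",
    "solve_sequential_two_site",
    "solve_cyclic_two_site",
    "solve_gst_dimer",
    "solve",
    "predict_fraction_unbound",
    "fraction_unbound",
    "bound_stoichiometry",
]

KINDS = ("single_site", "sequential_two_site", "cyclic_two_site", "gst_dimer")

#: parameters each mechanism requires, in canonical order
PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "single_site": ("K_D_D",),
    "sequential_two_site": ("K_D_D", "K_D_A_D"),
    "cyclic_two_site": ("K_D_D", "K_D_A", "alpha"),
    "gst_dimer": ("K_D_A", "K_D_Aprime"),
}

#: Rac1 monomers carried by each complex species
RAC_PER_SPECIES = {"WR": 1, "WR_D": 1, "WR_A": 1, "WR_DA": 2, "G2": 2, "G2W": 2, "G2W2": 2}
#: WRC copies carried by each complex species
WRC_PER_SPECIES = {"WR": 1, "WR_D": 1, "WR_A": 1, "WR_DA": 1, "G2": 0, "G2W": 1, "G2W2": 2}

_BISECT_ITERS = 64  # interval shrinks 2^-64: beyond double-precision resolution


def _require_positive_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or value <= 0.0:
        raise ParameterDomainError(f"{name} must be positive and finite, got {value!r}")
    return value


@dataclass(frozen=True)
class MechanismSpec:
    """A binding mechanism and its dissociation constants (uM).

    ``parameters`` holds exactly the constants the mechanism requires (see
    :data:`PARAM_NAMES`); ``alpha`` for the cyclic mechanism is the
    dimensionless cooperativity, K_D_A(D) = K_D_A / alpha.
    """

    kind: str
    parameters: Mapping[str, float]

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ParameterDomainError(f"unknown mechanism kind {self.kind!r}; expected one of {KINDS}")
        required = PARAM_NAMES[self.kind]
        got = tuple(sorted(self.parameters))
        if got != tuple(sorted(required)):
            raise ParameterDomainError(
                f"mechanism {self.kind!r} requires parameters {required}, got {got}"
            )
        clean = {name: _require_positive_finite(name, self.parameters[name]) for name in required}
        object.__setattr__(self, "parameters", clean)

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def single_site(cls, kd_d: float) -> "MechanismSpec":
        return cls("single_site", {"K_D_D": kd_d})

    @classmethod
    def sequential_two_site(cls, kd_d: float, kd_ad: float) -> "MechanismSpec":
        return cls("sequential_two_site", {"K_D_D": kd_d, "K_D_A_D": kd_ad})

    @classmethod
    def cyclic_two_site(cls, kd_d: float, kd_a: float, alpha: float = 1.0) -> "MechanismSpec":
        return cls("cyclic_two_site", {"K_D_D": kd_d, "K_D_A": kd_a, "alpha": alpha})

    @classmethod
    def gst_dimer(cls, kd_a: float, kd_aprime: float) -> "MechanismSpec":
        return cls("gst_dimer", {"K_D_A": kd_a, "K_D_Aprime": kd_aprime})

    def param_vector(self) -> np.ndarray:
        return np.array([self.parameters[n] for n in PARAM_NAMES[self.kind]], dtype=float)


@dataclass(frozen=True)
class MixtureSpec:
    """Total (conserved) concentrations, uM.

    ``ligand_total`` counts Rac1 monomers even for the GST-dimer mechanism,
    matching how experimental GST-Rac1 concentrations are reported; the
    dimer total used internally is ``ligand_total / 2``.
    """

    receptor_total: float
    ligand_total: float

    def __post_init__(self):
        for name in ("receptor_total", "ligand_total"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0.0:
                raise ParameterDomainError(f"{name} must be finite and >= 0, got {v!r}")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class EquilibriumState:
    """Solved free and complexed species concentrations (uM) for one mixture."""

    mechanism_kind: str
    receptor_total: float
    ligand_total: float
    free_receptor: float
    free_ligand: float
    species: Mapping[str, float]

    def to_dict(self) -> dict:
        return {
            "mechanism_kind": self.mechanism_kind,
            "receptor_total": self.receptor_total,
            "ligand_total": self.ligand_total,
            "free_receptor": self.free_receptor,
            "free_ligand": self.free_ligand,
            "species": dict(self.species),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "EquilibriumState":
        d = json.loads(text)
        return cls(
            mechanism_kind=d["mechanism_kind"],
            receptor_total=d["receptor_total"],
            ligand_total=d["ligand_total"],
            free_receptor=d["free_receptor"],
            free_ligand=d["free_ligand"],
            species=dict(d["species"]),
        )

    def conservation_residuals(self) -> tuple[float, float]:
        """Relative receptor and ligand conservation residuals.

        Receptor species are counted once per WRC copy; WR_DA carries two
        Rac1, G2-containing species carry the dimer's two Rac1.
        """
        w = self.free_receptor + sum(
            WRC_PER_SPECIES[name] * conc for name, conc in self.species.items()
        )
        if self.mechanism_kind == "gst_dimer":
            # free ligand is the free GST dimer (2 Rac1 each)
            r = 2.0 * self.free_ligand + sum(
                RAC_PER_SPECIES[name] * conc
                for name, conc in self.species.items()
                if name != "G2"  # free dimer already counted via free_ligand
            )
        else:
            r = self.free_ligand + sum(
                RAC_PER_SPECIES[name] * conc for name, conc in self.species.items()
            )
        res_w = abs(w - self.receptor_total) / max(self.receptor_total, 1.0)
        res_r = abs(r - self.ligand_total) / max(self.ligand_total, 1.0)
        return res_w, res_r


def _brent(f, lo: float, hi: float) -> float:
    flo, fhi = f(lo), f(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    assert flo < 0.0 < fhi, "conservation residual must bracket the root"
    return brentq(f, lo, hi, xtol=1e-24, rtol=4 * np.finfo(float).eps, maxiter=200)


def solve_single_site(mix: MixtureSpec, kd: float) -> EquilibriumState:
    """One Rac1 site; [WR] from the depletion quadratic, numerically stable form."""
    kd = _require_positive_finite("kd", kd)
    w_tot, r_tot = mix.receptor_total, mix.ligand_total
    b = w_tot + r_tot + kd
    disc = math.sqrt(b * b - 4.0 * w_tot * r_tot)
    wr = 2.0 * w_tot * r_tot / (b + disc)
    return EquilibriumState(
        mechanism_kind="single_site",
        receptor_total=w_tot,
        ligand_total=r_tot,
        free_receptor=w_tot - wr,
        free_ligand=r_tot - wr,
        species={"WR": wr},
    )


def _two_site_coeffs(mech: MechanismSpec) -> tuple[float, float]:
    """Binding-polynomial coefficients c1, c2 so Q(r) = 1 + c1 r + c2 r^2."""
    p = mech.parameters
    if mech.kind == "sequential_two_site":
        return 1.0 / p["K_D_D"], 1.0 / (p["K_D_D"] * p["K_D_A_D"])
    if mech.kind == "cyclic_two_site":
        return (
            1.0 / p["K_D_D"] + 1.0 / p["K_D_A"],
            p["alpha"] / (p["K_D_D"] * p["K_D_A"]),
        )
    raise ParameterDomainError(f"not a two-site mechanism: {mech.kind}")


def _solve_two_site_free_ligand(w_tot: float, r_tot: float, c1: float, c2: float) -> float:
    """Free Rac1 monomer r in [0, r_tot] from ligand conservation.

    r + w_tot * (c1 r + 2 c2 r^2) / (1 + c1 r + c2 r^2) = r_tot; the left
    side is strictly increasing in r, so the root is unique and bracketed.
    """
    if r_tot == 0.0:
        return 0.0
    if w_tot == 0.0:
        return r_tot

    def residual(r: float) -> float:
        q = 1.0 + r * (c1 + c2 * r)
        return r + w_tot * r * (c1 + 2.0 * c2 * r) / q - r_tot

    return _brent(residual, 0.0, r_tot)


def solve_sequential_two_site(mix: MixtureSpec, kd_d: float, kd_ad: float) -> EquilibriumState:
    """D site fills first (K_D_D), then the A site on the D-bound complex (K_D_A_D)."""
    mech = MechanismSpec.sequential_two_site(kd_d, kd_ad)
    c1, c2 = _two_site_coeffs(mech)
    w_tot, r_tot = mix.receptor_total, mix.ligand_total
    r = _solve_two_site_free_ligand(w_tot, r_tot, c1, c2)
    q = 1.0 + r * (c1 + c2 * r)
    w = w_tot / q
    return EquilibriumState(
        mechanism_kind="sequential_two_site",
        receptor_total=w_tot,
        ligand_total=r_tot,
        free_receptor=w,
        free_ligand=r,
        species={"WR_D": w * c1 * r, "WR_DA": w * c2 * r * r},
    )


def solve_cyclic_two_site(mix: MixtureSpec, kd_d: float, kd_a: float, alpha: float) -> EquilibriumState:
    """Independent D and A sites joined in a thermodynamic cycle.

    [WR_DA] = alpha [W] r^2 / (K_D_D K_D_A); alpha > 1 is positive
    cooperativity, alpha = 1 makes the two occupancies independent.
    """
    mech = MechanismSpec.cyclic_two_site(kd_d, kd_a, alpha)
    c1, c2 = _two_site_coeffs(mech)
    w_tot, r_tot = mix.receptor_total, mix.ligand_total
    r = _solve_two_site_free_ligand(w_tot, r_tot, c1, c2)
    q = 1.0 + r * (c1 + c2 * r)
    w = w_tot / q
    return EquilibriumState(
        mechanism_kind="cyclic_two_site",
        receptor_total=w_tot,
        ligand_total=r_tot,
        free_receptor=w,
        free_ligand=r,
        species={
            "WR_D": w * r / kd_d,
            "WR_A": w * r / kd_a,
            "WR_DA": w * alpha * r * r / (kd_d * kd_a),
        },
    )


def solve_gst_dimer(mix: MixtureSpec, kd_a: float, kd_aprime: float) -> EquilibriumState:
    """Dimeric GST-Rac1 binding one then two WRCs.

    The dimer total is ``ligand_total / 2`` (ligand totals count Rac1
    monomers).  Solved by root-finding on free WRC w in [0, receptor_total];
    ``free_ligand`` in the returned state is the free GST dimer G2.
    """
    mech = MechanismSpec.gst_dimer(kd_a, kd_aprime)
    p = mech.parameters
    c1 = 1.0 / p["K_D_A"]
    c2 = 1.0 / (p["K_D_A"] * p["K_D_Aprime"])
    w_tot = mix.receptor_total
    g2_tot = mix.ligand_total / 2.0

    if w_tot == 0.0 or g2_tot == 0.0:
        w = w_tot
        g2 = g2_tot
    else:

        def residual(w: float) -> float:
            q = 1.0 + w * (c1 + c2 * w)
            return w + g2_tot * w * (c1 + 2.0 * c2 * w) / q - w_tot

        w = _brent(residual, 0.0, w_tot)
        g2 = g2_tot / (1.0 + w * (c1 + c2 * w))

    return EquilibriumState(
        mechanism_kind="gst_dimer",
        receptor_total=w_tot,
        ligand_total=mix.ligand_total,
        free_receptor=w,
        free_ligand=g2,
        species={"G2W": g2 * c1 * w, "G2W2": g2 * c2 * w * w},
    )


def solve(mech: MechanismSpec, mix: MixtureSpec) -> EquilibriumState:
    """Dispatch to the mechanism-specific solver."""
    p = mech.parameters
    if mech.kind == "single_site":
        return solve_single_site(mix, p["K_D_D"])
    if mech.kind == "sequential_two_site":
        return solve_sequential_two_site(mix, p["K_D_D"], p["K_D_A_D"])
    if mech.kind == "cyclic_two_site":
        return solve_cyclic_two_site(mix, p["K_D_D"], p["K_D_A"], p["alpha"])
    return solve_gst_dimer(mix, p["K_D_A"], p["K_D_Aprime"])


# ---------------------------------------------------------------------------
# vectorized titration path (used by fitting and the generators)
# ---------------------------------------------------------------------------

def _bisect_vec(residual, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Vectorized bisection; the residual must be increasing with a root in [lo, hi]."""
    lo = lo.copy()
    hi = hi.copy()
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (lo + hi)
        high = residual(mid) > 0.0
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    return 0.5 * (lo + hi)


def predict_fraction_unbound(
    mech: MechanismSpec,
    ligand_total: np.ndarray,
    receptor_total: float | np.ndarray,
) -> np.ndarray:
    """Fraction of WRC left free at equilibrium, over a whole titration.

    This is the equilibrium pull-down observable: every GST-containing
    species is bead-captured (GST/glutathione affinity is ~7 pM, far below
    any concentration used), so only ligand-free WRC remains in the
    supernatant.
    """
    r_tot = np.asarray(ligand_total, dtype=float)
    w_tot = np.broadcast_to(np.asarray(receptor_total, dtype=float), r_tot.shape).copy()
    if np.any(r_tot < 0) or np.any(w_tot <= 0):
        raise ParameterDomainError("ligand totals must be >= 0 and receptor totals > 0")
    p = mech.parameters

    if mech.kind == "single_site":
        kd = p["K_D_D"]
        b = w_tot + r_tot + kd
        wr = 2.0 * w_tot * r_tot / (b + np.sqrt(b * b - 4.0 * w_tot * r_tot))
        return (w_tot - wr) / w_tot

    if mech.kind in ("sequential_two_site", "cyclic_two_site"):
        c1, c2 = _two_site_coeffs(mech)

        def residual(r):
            q = 1.0 + r * (c1 + c2 * r)
            return r + w_tot * r * (c1 + 2.0 * c2 * r) / q - r_tot

        r = _bisect_vec(residual, np.zeros_like(r_tot), r_tot.copy())
        return 1.0 / (1.0 + r * (c1 + c2 * r))

    # gst_dimer: root on free WRC
    c1 = 1.0 / p["K_D_A"]
    c2 = 1.0 / (p["K_D_A"] * p["K_D_Aprime"])
    g2_tot = r_tot / 2.0

    def residual_w(w):
        q = 1.0 + w * (c1 + c2 * w)
        return w + g2_tot * w * (c1 + 2.0 * c2 * w) / q - w_tot

    w = _bisect_vec(residual_w, np.zeros_like(w_tot), w_tot.copy())
    return w / w_tot


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def fraction_unbound(state: EquilibriumState) -> float:
    """Free WRC over total WRC — the equilibrium pull-down observable."""
    if state.receptor_total <= 0.0:
        raise UndefinedObservableError("fraction unbound is undefined when receptor_total is 0")
    return state.free_receptor / state.receptor_total


def bound_stoichiometry(state: EquilibriumState, complexed_only: bool = False) -> float:
    """Rac1 monomers bound per WRC.

    Counts Rac1 carried by WRC-containing species (WR_DA and G2-containing
    complexes carry two).  By default the denominator is all WRC including
    free; ``complexed_only=True`` restricts it to WRC in complexes, which is
    the quantity reported for an isolated sedimenting complex peak.
    """
    rac_bound = sum(
        RAC_PER_SPECIES[name] * conc
        for name, conc in state.species.items()
        if WRC_PER_SPECIES[name] > 0
    )
    wrc_complexed = sum(WRC_PER_SPECIES[name] * conc for name, conc in state.species.items())
    denom = wrc_complexed if complexed_only else wrc_complexed + state.free_receptor
    if denom <= 0.0:
        raise UndefinedObservableError("no WRC in the requested denominator")
    return rac_bound / denom
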