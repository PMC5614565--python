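"""Linking Rac1-bound WRC species distributions to actin-assembly activity.

Under the bivalent activation model, only the doubly Rac1-bound complex
WRC-(Rac1)2 (species ``WR_DA``) stimulates Arp2/3-mediated actin assembly.
This module computes, across a Rac1 titration, the equilibrium
concentrations of all WRC species under the cyclic two-site mechanism with
no cooperativity (alpha = 1, appropriate for solution assays where no
avidity surface is present), then relates the measured maximum actin
assembly rate linearly to the concentration of a chosen species.  The slope
of that line is the specific activity (nM actin/s per nM of the species);
the doubly bound species should give a near-perfect line while the summed
bound species does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .equilibria import MechanismSpec, MixtureSpec, solve_cyclic_two_site
from .errors import InsufficientDataError, ParameterDomainError

__all__ = ["SpeciesSeries", "ActivityFit", "species_distribution", "fit_specific_activity"]

# default dissociation constants (uM) for the intact D and A sites
DEFAULT_KD_D = 0.265
DEFAULT_KD_A = 11.52
DEFAULT_W_TOT = 0.1


@dataclass
class SpeciesSeries:
    """Equilibrium WRC species concentrations (uM) over a Rac1 titration."""

    ligand_total: np.ndarray
    W: np.ndarray
    WR_D: np.ndarray
    WR_A: np.ndarray
    WR_DA: np.ndarray
    kd_D: float
    kd_A: float
    receptor_total: float

    @property
    def sum_bound(self) -> np.ndarray:
        """Total Rac1-bound WRC: singly (either site) plus doubly bound."""
        return self.WR_D + self.WR_A + self.WR_DA

    def species(self, label: str) -> np.ndarray:
        if label == "sum_bound":
            return self.sum_bound
        try:
            return getattr(self, label)
        except AttributeError:
            raise ParameterDomainError(f"unknown species label {label!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand_total_uM": self.ligand_total,
                "W_uM": self.W,
                "WR_D_uM": self.WR_D,
                "WR_A_uM": self.WR_A,
                "WR_DA_uM": self.WR_DA,
                "sum_bound_uM": self.sum_bound,
            }
        )


@dataclass
class ActivityFit:
    """Ordinary least-squares line of assembly rate vs species concentration."""

    slope: float  # nM actin/s per nM of the species
    intercept: float  # nM/s, baseline assembly without activator
    r_squared: float
    species_used: str
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope_nM_per_s_per_nM": self.slope,
            "intercept_nM_per_s": self.intercept,
            "r_squared": self.r_squared,
            "species_used": self.species_used,
            "n_points": self.n_points,
        }


def species_distribution(
    ligand_totals,
    kd_D: float = DEFAULT_KD_D,
    kd_A: float = DEFAULT_KD_A,
    w_tot: float = DEFAULT_W_TOT,
) -> SpeciesSeries:
    """WRC species concentrations per titration point, cyclic model, alpha = 1.

    With alpha = 1 the two site occupancies are independent at the solved
    free Rac1 concentration, so WR_DA = W_tot * p_D * p_A with
    p_site = r / (r + K_D_site).
    """
    MechanismSpec.cyclic_two_site(kd_D, kd_A, 1.0)  # validates constants
    ligand_totals = np.atleast_1d(np.asarray(ligand_totals, dtype=float))
    cols = {"W": [], "WR_D": [], "WR_A": [], "WR_DA": []}
    for r_tot in ligand_totals:
        state = solve_cyclic_two_site(MixtureSpec(w_tot, float(r_tot)), kd_D, kd_A, 1.0)
        cols["W"].append(state.free_receptor)
        for name in ("WR_D", "WR_A", "WR_DA"):
            cols[name].append(state.species[name])
    return SpeciesSeries(
        ligand_total=ligand_totals,
        W=np.array(cols["W"]),
        WR_D=np.array(cols["WR_D"]),
        WR_A=np.array(cols["WR_A"]),
        WR_DA=np.array(cols["WR_DA"]),
        kd_D=kd_D,
        kd_A=kd_A,
        receptor_total=w_tot,
    )


def fit_specific_activity(
    series: SpeciesSeries,
    rates,
    species: str = "WR_DA",
) -> ActivityFit:
    """Fit rate = slope * [species] + intercept by ordinary least squares.

    ``rates`` are maximum actin assembly rates in nM/s, one per titration
    point; species concentrations are converted from uM to nM so the slope
    is a specific activity in nM actin/s per nM of the species.  The
    intercept is left free: Arp2/3 plus WRC alone assembles actin slowly,
    giving a nonzero baseline rate.
    """
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    x_nM = series.species(species) * 1e3
    if rates.shape != x_nM.shape:
        raise ParameterDomainError("rates and species series must have equal length")
    if rates.size < 3:
        raise InsufficientDataError("a linear fit needs at least 3 points")
    if np.ptp(x_nM) == 0.0:
        raise ParameterDomainError("species concentration is constant; slope is undefined")
    res = stats.linregress(x_nM, rates)
    # r^2 from the regression SS so a flat response gives exactly 0
    pred = res.intercept + res.slope * x_nM
    ss_tot = float(np.sum((rates - rates.mean()) ** 2))
    r2 = 1.0 - float(np.sum((rates - pred) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return ActivityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r2,
        species_used=species,
        n_points=rates.size,
    )
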