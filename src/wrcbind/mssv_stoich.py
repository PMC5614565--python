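"""Multi-signal sedimentation-velocity stoichiometry.

In a multi-signal AUC experiment the same sedimenting boundary is recorded
with two optical systems.  Here EGFP-Rac1 is tracked by absorbance at
490 nm (only EGFP absorbs there) and by interference, while the WRC
contributes to interference only.  Given per-molar signal increments, the
pair of signal densities over sedimentation coefficient s is decomposed
algebraically, per s value, into component concentration distributions
c_k(s):

    A(s)  = eps_490 * l * c_Rac(s)
    IF(s) = l * (f_Rac * c_Rac(s) + f_WRC * c_WRC(s))

Integrating c_k(s) over a peak range gives each component's concentration
in that species, hence the Rac1:WRC molar ratio, and the signal-average
sedimentation coefficient is the interference-weighted mean of s over the
range.  The hydrodynamic c(s) inversion that produces the signal
distributions is upstream of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DecompositionError, ParameterDomainError, UndefinedRatioError

__all__ = [
    "SignalIncrements",
    "SignalDistributions",
    "CkDistribution",
    "StoichiometryResult",
    "decompose",
    "integrate_stoichiometry",
    "titration_summary",
]

# calibrated extinction coefficient of (incompletely matured) EGFP-Rac1 at 490 nm
DEFAULT_EPSILON_490 = 32310.8  # AU / (M cm)
DEFAULT_FRINGE_RAC = 141801.0  # fringes / (M cm), EGFP-Rac1
DEFAULT_FRINGE_WRC = 904251.0  # fringes / (M cm), WRC
DEFAULT_PATH_LENGTH = 1.2  # cm, dual-sector centerpiece

MAX_CONDITION_NUMBER = 1e6


@dataclass(frozen=True)
class SignalIncrements:
    """Per-molar optical signals of the two components and the optical path."""

    epsilon_490: float = DEFAULT_EPSILON_490
    fringe_rac: float = DEFAULT_FRINGE_RAC
    fringe_wrc: float = DEFAULT_FRINGE_WRC
    path_length: float = DEFAULT_PATH_LENGTH

    def __post_init__(self):
        for name in ("epsilon_490", "fringe_rac", "fringe_wrc", "path_length"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ParameterDomainError(f"{name} must be positive and finite, got {v!r}")
            object.__setattr__(self, name, v)

    def matrix(self) -> np.ndarray:
        """2x2 map from (c_Rac, c_WRC) in M to (absorbance, interference) densities."""
        l = self.path_length
        return np.array(
            [[self.epsilon_490 * l, 0.0], [self.fringe_rac * l, self.fringe_wrc * l]]
        )


@dataclass
class SignalDistributions:
    """Absorbance and interference signal densities over sedimentation coefficient."""

    s_grid: np.ndarray  # Svedberg, strictly increasing
    absorbance_density: np.ndarray  # AU per S
    interference_density: np.ndarray  # fringes per S

    def __post_init__(self):
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.absorbance_density = np.asarray(self.absorbance_density, dtype=float)
        self.interference_density = np.asarray(self.interference_density, dtype=float)
        if not (self.s_grid.shape == self.absorbance_density.shape == self.interference_density.shape):
            raise ParameterDomainError("signal columns must share the s grid length")
        if self.s_grid.ndim != 1 or self.s_grid.size < 2 or np.any(np.diff(self.s_grid) <= 0):
            raise ParameterDomainError("s grid must be 1-D and strictly increasing")


@dataclass
class CkDistribution:
    """Component molar concentration densities (M per S) over the s grid."""

    s_grid: np.ndarray
    rac_density: np.ndarray
    wrc_density: np.ndarray
    interference_density: np.ndarray  # carried through as the s-average weight
    has_negative: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s_svedberg": self.s_grid,
                "rac_density_M_per_S": self.rac_density,
                "wrc_density_M_per_S": self.wrc_density,
            }
        )


@dataclass
class StoichiometryResult:
    """Integrated peak concentrations and molar ratio over one s range."""

    s_range: tuple[float, float]
    rac_conc: float  # uM
    wrc_conc: float  # uM
    ratio: float  # Rac1 per WRC
    s_weighted: float  # Svedberg, interference-weighted

    def to_dict(self) -> dict:
        return {
            "s_range": list(self.s_range),
            "rac_conc_uM": self.rac_conc,
            "wrc_conc_uM": self.wrc_conc,
            "ratio_rac_per_wrc": self.ratio,
            "s_weighted_S": self.s_weighted,
        }


def decompose(signals: SignalDistributions, inc: SignalIncrements) -> CkDistribution:
    """Invert the 2x2 signal system at every s value.

    c_Rac = A / (eps * l); c_WRC = (IF / l - f_Rac * c_Rac) / f_WRC.
    Negative concentrations are retained and flagged (``has_negative``):
    negativity diagnoses misspecified signal increments rather than being
    silently floored.
    """
    m = inc.matrix()
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond >= MAX_CONDITION_NUMBER:
        raise DecompositionError(
            f"signal-increment system is ill-conditioned (condition number {cond:.3g})"
        )
    l = inc.path_length
    c_rac = signals.absorbance_density / (inc.epsilon_490 * l)
    c_wrc = (signals.interference_density / l - inc.fringe_rac * c_rac) / inc.fringe_wrc
    return CkDistribution(
        s_grid=signals.s_grid,
        rac_density=c_rac,
        wrc_density=c_wrc,
        interference_density=signals.interference_density,
        has_negative=bool(np.any(c_rac < 0) or np.any(c_wrc < 0)),
    )


def integrate_stoichiometry(
    ck: CkDistribution,
    s_range: tuple[float, float],
    floor_negative: bool = False,
) -> StoichiometryResult:
    """Trapezoidal peak integrals, molar ratio, and signal-average s.

    The signal-average sedimentation coefficient is the mean of s weighted
    by the total interference density over the range.  ``floor_negative``
    clips negative densities to zero during integration only; the
    distribution itself is untouched.
    """
    lo, hi = float(s_range[0]), float(s_range[1])
    s = ck.s_grid
    if lo >= hi:
        raise ParameterDomainError("s_range must be (low, high) with low < high")
    if lo < s[0] or hi > s[-1]:
        raise ParameterDomainError(f"s_range {s_range} extends beyond the grid [{s[0]}, {s[-1]}]")
    mask = (s >= lo) & (s <= hi)
    if mask.sum() < 3:
        raise ParameterDomainError("s_range must cover at least 3 grid points")
    sv = s[mask]
    rac = ck.rac_density[mask]
    wrc = ck.wrc_density[mask]
    weight = ck.interference_density[mask]
    if floor_negative:
        rac = np.clip(rac, 0.0, None)
        wrc = np.clip(wrc, 0.0, None)
    rac_m = float(np.trapezoid(rac, sv))
    wrc_m = float(np.trapezoid(wrc, sv))
    # a ratio over a range with no real WRC signal (zero, negative, or
    # vanishing next to the Rac signal) is meaningless
    if wrc_m <= 0.0 or (rac_m > 0.0 and wrc_m < 1e-9 * rac_m):
        raise UndefinedRatioError(
            f"WRC integral over {s_range} is {wrc_m:.3g} M; the Rac:WRC ratio is undefined"
        )
    w_int = float(np.trapezoid(weight, sv))
    s_weighted = float(np.trapezoid(weight * sv, sv) / w_int) if w_int != 0 else float("nan")
    return StoichiometryResult(
        s_range=(lo, hi),
        rac_conc=rac_m * 1e6,
        wrc_conc=wrc_m * 1e6,
        ratio=rac_m / wrc_m,
        s_weighted=s_weighted,
    )


def titration_summary(
    samples: Sequence[tuple[float, CkDistribution, tuple[float, float]]],
    floor_negative: bool = False,
) -> pd.DataFrame:
    """Stoichiometry table for a titration of decomposed distributions.

    ``samples`` are (total Rac1 uM, distribution, peak s range) triples;
    per-sample failures are recorded in an ``error`` column rather than
    aborting the rest.
    """
    rows = []
    for rac_total, ck, s_range in samples:
        row = {
            "rac_total_uM": float(rac_total),
            "s_weighted_S": np.nan,
            "ratio_rac_per_wrc": np.nan,
            "rac_conc_uM": np.nan,
            "wrc_conc_uM": np.nan,
            "error": "",
        }
        try:
            res = integrate_stoichiometry(ck, s_range, floor_negative=floor_negative)
            row.update(
                s_weighted_S=res.s_weighted,
                ratio_rac_per_wrc=res.ratio,
                rac_conc_uM=res.rac_conc,
                wrc_conc_uM=res.wrc_conc,
            )
        except Exception as exc:
            row["error"] = repr(exc)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["rac_total_uM", "s_weighted_S", "ratio_rac_per_wrc", "rac_conc_uM", "wrc_conc_uM", "error"],
    )
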