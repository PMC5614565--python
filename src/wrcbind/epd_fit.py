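"""Fitting equilibrium pull-down isotherms and quantifying their uncertainty.

An equilibrium pull-down (EPD) titration mixes a fixed concentration of WRC
with increasing GST-Rac1 plus glutathione beads; after pelleting, the
fraction of WRC left in the supernatant is quantified by gel densitometry.
This module fits such isotherms to any of the mechanisms in
:mod:`wrcbind.equilibria`, discriminates nested mechanisms with the
extra-sum-of-squares F-test, and estimates parameter uncertainty by a
residual-shuffle Monte Carlo.

Fitting conventions
-------------------
* Unweighted least squares on the fraction-unbound observable.  Replicate
  experiments are pooled directly into one isotherm, so each point carries
  equal weight.
* Dissociation constants (and the cyclic cooperativity alpha) are fit in
  log10 space with bounds 1e-4 to 1e4 uM, since the constants of interest
  span three orders of magnitude (0.03 to 12 uM).
* Local least-squares minimization from a multi-start grid, default
  log10 K in {-2, -1, 0, 1, 2} per parameter; ties are broken by lowest SSR
  then lexicographically smallest parameter vector, so a fit is
  deterministic given the same inputs and start grid.
* The "shuffle" Monte Carlo permutes residuals across points without
  replacement (pseudo-data = fitted + permuted residuals, then refit); a
  bootstrap (sampling residuals with replacement) is available via
  ``method="bootstrap"``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .equilibria import KINDS, PARAM_NAMES, MechanismSpec, predict_fraction_unbound
from .errors import (
    ComparisonDomainError,
    InsufficientDataError,
    NonConvergenceError,
    ParameterDomainError,
)

__all__ = [
    "Isotherm",
    "FitResult",
    "ModelComparison",
    "MonteCarloResult",
    "FitReport",
    "fit_isotherm",
    "f_test",
    "monte_carlo_errors",
    "fit_report",
    "DEFAULT_BOUNDS",
    "DEFAULT_MC_ITERATIONS",
]

DEFAULT_BOUNDS = (1e-4, 1e4)  # uM, on every fitted constant
DEFAULT_START_DECADES = (-2.0, -1.0, 0.0, 1.0, 2.0)
DEFAULT_MC_ITERATIONS = 5000
MAX_OBSERVED_FRACTION = 1.2  # gel noise can push points slightly above 1
MIN_POINTS = 6


@dataclass
class Isotherm:
    """One pooled equilibrium pull-down titration.

    Arrays are aligned per point: total GST-Rac1 (uM, counted per Rac1
    monomer), total WRC (uM), and the observed fraction of WRC remaining in
    the supernatant.
    """

    ligand_total: np.ndarray
    receptor_total: np.ndarray
    fraction_unbound: np.ndarray
    label: str = ""
    provenance: str = ""

    def __post_init__(self):
        self.ligand_total = np.atleast_1d(np.asarray(self.ligand_total, dtype=float))
        self.receptor_total = np.broadcast_to(
            np.asarray(self.receptor_total, dtype=float), self.ligand_total.shape
        ).copy()
        self.fraction_unbound = np.atleast_1d(np.asarray(self.fraction_unbound, dtype=float))
        if not (self.ligand_total.shape == self.fraction_unbound.shape):
            raise ParameterDomainError("isotherm columns must have equal length")
        if np.any(self.ligand_total < 0):
            raise ParameterDomainError("ligand totals must be >= 0")
        if np.any(self.receptor_total <= 0):
            raise ParameterDomainError("receptor totals must be > 0")
        if not np.all(np.isfinite(self.fraction_unbound)):
            raise ParameterDomainError("observed fractions must be finite")
        if np.any(self.fraction_unbound > MAX_OBSERVED_FRACTION):
            raise ParameterDomainError(
                f"observed fractions above {MAX_OBSERVED_FRACTION} are not plausible gel readings"
            )

    def __len__(self) -> int:
        return self.ligand_total.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand_total_uM": self.ligand_total,
                "receptor_total_uM": self.receptor_total,
                "fraction_unbound": self.fraction_unbound,
            }
        )


@dataclass
class FitResult:
    """Best-fit mechanism for one isotherm, with the fit diagnostics."""

    mechanism: MechanismSpec
    ssr: float
    n_points: int
    n_params: int
    fitted_curve: np.ndarray
    converged: bool
    starts_tried: int
    isotherm_label: str = ""

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[self.mechanism.kind]

    @property
    def params(self) -> dict[str, float]:
        return dict(self.mechanism.parameters)

    def to_dict(self) -> dict:
        return {
            "mechanism_kind": self.mechanism.kind,
            "parameters": self.params,
            "ssr": self.ssr,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "converged": self.converged,
            "starts_tried": self.starts_tried,
            "isotherm_label": self.isotherm_label,
            "fitted_curve": np.asarray(self.fitted_curve).tolist(),
        }


@dataclass
class ModelComparison:
    """Extra-sum-of-squares F-test between two nested fits."""

    f_statistic: float
    df_numerator: int
    df_denominator: int
    p_value: float
    preferred: str
    simple_label: str = ""
    complex_label: str = ""

    def to_dict(self) -> dict:
        return {
            "f_statistic": self.f_statistic,
            "df_numerator": self.df_numerator,
            "df_denominator": self.df_denominator,
            "p_value": self.p_value,
            "preferred": self.preferred,
            "simple_label": self.simple_label,
            "complex_label": self.complex_label,
        }


@dataclass
class MonteCarloResult:
    """Residual-shuffle Monte Carlo uncertainty for one fit."""

    param_names: tuple[str, ...]
    estimates: dict[str, float]
    standard_errors: dict[str, float]
    ci68: dict[str, tuple[float, float]]
    ci95: dict[str, tuple[float, float]]
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]
    draws: np.ndarray  # shape (n_kept, n_params)
    n_iterations: int
    n_dropped: int
    seed: int
    method: str
    high_drop_rate: bool

    def decade_span(self, name: str) -> float:
        """log10 span of the accepted draws for one parameter (identifiability check)."""
        j = self.param_names.index(name)
        col = self.draws[:, j]
        col = col[col > 0]
        if col.size == 0:
            return math.inf
        return float(np.log10(col.max()) - np.log10(col.min()))

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "estimates": self.estimates,
            "standard_errors": self.standard_errors,
            "ci68": {k: list(v) for k, v in self.ci68.items()},
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "n_iterations": self.n_iterations,
            "n_dropped": self.n_dropped,
            "seed": self.seed,
            "method": self.method,
            "high_drop_rate": self.high_drop_rate,
        }


def _log_bounds(bounds: tuple[float, float]) -> tuple[float, float]:
    lo, hi = bounds
    if not (0 < lo < hi) or not (math.isfinite(lo) and math.isfinite(hi)):
        raise ParameterDomainError(f"bounds must satisfy 0 < lo < hi, got {bounds}")
    return math.log10(lo), math.log10(hi)


def _mechanism_from_log10(kind: str, x: np.ndarray) -> MechanismSpec:
    names = PARAM_NAMES[kind]
    return MechanismSpec(kind, {n: 10.0 ** xi for n, xi in zip(names, x)})


def _residuals(x: np.ndarray, kind: str, iso: Isotherm) -> np.ndarray:
    mech = _mechanism_from_log10(kind, x)
    pred = predict_fraction_unbound(mech, iso.ligand_total, iso.receptor_total)
    return iso.fraction_unbound - pred


def _single_local_fit(kind: str, iso: Isotherm, x0: np.ndarray, lb: float, ub: float):
    return least_squares(
        _residuals,
        np.clip(x0, lb, ub),
        bounds=(lb, ub),
        args=(kind, iso),
        method="trf",
        xtol=1e-12,
        ftol=1e-14,
        gtol=1e-12,
        max_nfev=400,
    )


def default_start_grid(kind: str) -> list[np.ndarray]:
    names = PARAM_NAMES[kind]
    return [np.array(combo) for combo in itertools.product(DEFAULT_START_DECADES, repeat=len(names))]


def fit_isotherm(
    iso: Isotherm,
    kind: str,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    starts: Sequence[Sequence[float]] | None = None,
) -> FitResult:
    """Least-squares fit of one mechanism to one isotherm.

    ``starts`` are log10-space start vectors; the default is the full grid
    of :data:`DEFAULT_START_DECADES` per parameter.  The global candidate is
    the start with the lowest SSR (ties: smallest parameter vector), making
    the result deterministic.
    """
    if kind not in KINDS:
        raise ParameterDomainError(f"unknown mechanism kind {kind!r}")
    names = PARAM_NAMES[kind]
    n, p = len(iso), len(names)
    if n < max(MIN_POINTS, p + 2):
        raise InsufficientDataError(
            f"{n} points is too few to fit {kind} ({p} parameters); need >= {max(MIN_POINTS, p + 2)}"
        )
    lb, ub = _log_bounds(bounds)
    start_vectors = (
        [np.asarray(s, dtype=float) for s in starts] if starts is not None else default_start_grid(kind)
    )
    if not start_vectors or any(s.shape != (p,) for s in start_vectors):
        raise ParameterDomainError(f"each start must have {p} entries (log10 uM)")

    candidates = []
    diagnostics = []
    for x0 in start_vectors:
        try:
            sol = _single_local_fit(kind, iso, x0, lb, ub)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append({"start": x0.tolist(), "error": repr(exc)})
            continue
        ssr = float(np.dot(sol.fun, sol.fun))
        if sol.success and math.isfinite(ssr):
            candidates.append((ssr, tuple(sol.x), sol))
        else:
            diagnostics.append({"start": x0.tolist(), "status": sol.status, "ssr": ssr})
    if not candidates:
        raise NonConvergenceError(
            f"no start converged for mechanism {kind!r}", diagnostics=diagnostics
        )
    ssr, xbest, sol = min(candidates, key=lambda c: (c[0], c[1]))
    mech = _mechanism_from_log10(kind, np.asarray(xbest))
    fitted = predict_fraction_unbound(mech, iso.ligand_total, iso.receptor_total)
    return FitResult(
        mechanism=mech,
        ssr=ssr,
        n_points=n,
        n_params=p,
        fitted_curve=fitted,
        converged=True,
        starts_tried=len(start_vectors),
        isotherm_label=iso.label,
    )


def f_test(simple: FitResult, complex_: FitResult, alpha: float = 0.05) -> ModelComparison:
    """Extra-sum-of-squares F-test of a nested pair of fits on the same isotherm.

    F = ((SSR_s - SSR_c) / (p_c - p_s)) / (SSR_c / (n - p_c)), with p-value
    from the F(p_c - p_s, n - p_c) upper tail.  If the complex model does
    not improve the SSR, F is clamped to 0 and p = 1.
    """
    if simple.n_points != complex_.n_points or simple.isotherm_label != complex_.isotherm_label:
        raise ComparisonDomainError("fits were made on different isotherms")
    if complex_.n_params <= simple.n_params:
        raise ComparisonDomainError("the complex model must have more parameters")
    n = simple.n_points
    df1 = complex_.n_params - simple.n_params
    df2 = n - complex_.n_params
    if df2 <= 0:
        raise ComparisonDomainError("no residual degrees of freedom for the complex model")
    if complex_.ssr >= simple.ssr or complex_.ssr <= 0.0:
        f_stat, p = (0.0, 1.0) if complex_.ssr >= simple.ssr else (math.inf, 0.0)
    else:
        f_stat = ((simple.ssr - complex_.ssr) / df1) / (complex_.ssr / df2)
        p = float(stats.f.sf(f_stat, df1, df2))
    preferred = complex_.mechanism.kind if p < alpha else simple.mechanism.kind
    return ModelComparison(
        f_statistic=f_stat,
        df_numerator=df1,
        df_denominator=df2,
        p_value=p,
        preferred=preferred,
        simple_label=simple.mechanism.kind,
        complex_label=complex_.mechanism.kind,
    )


def monte_carlo_errors(
    fit: FitResult,
    iso: Isotherm,
    n_iter: int = DEFAULT_MC_ITERATIONS,
    seed: int = 0,
    method: str = "shuffle",
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
) -> MonteCarloResult:
    """Parameter uncertainty by refitting residual-permuted pseudo-data.

    Each iteration permutes the fit residuals across points ("shuffle",
    without replacement) or resamples them with replacement ("bootstrap"),
    adds them to the fitted curve, and refits from the converged solution.
    Refits that fail to converge are dropped and counted; a drop rate above
    20% raises the ``high_drop_rate`` flag.
    """
    if not fit.converged:
        raise ParameterDomainError("Monte Carlo uncertainty requires a converged fit")
    if method not in ("shuffle", "bootstrap"):
        raise ParameterDomainError(f"unknown Monte Carlo method {method!r}")
    if n_iter < 1:
        raise ParameterDomainError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    names = fit.param_names
    lb, ub = _log_bounds(bounds)
    x_hat = np.log10(fit.mechanism.param_vector())
    fitted = np.asarray(fit.fitted_curve, dtype=float)
    resid = iso.fraction_unbound - fitted
    n = len(iso)

    draws = []
    n_dropped = 0
    for _ in range(n_iter):
        idx = rng.permutation(n) if method == "shuffle" else rng.integers(0, n, size=n)
        pseudo = Isotherm(
            ligand_total=iso.ligand_total,
            receptor_total=iso.receptor_total,
            fraction_unbound=np.clip(fitted + resid[idx], 0.0, MAX_OBSERVED_FRACTION),
            label=iso.label,
        )
        sol = _single_local_fit(fit.mechanism.kind, pseudo, x_hat, lb, ub)
        if sol.success and np.all(np.isfinite(sol.x)):
            draws.append(10.0 ** sol.x)
        else:
            n_dropped += 1
    draws = np.asarray(draws, dtype=float).reshape(-1, len(names))
    if draws.shape[0] == 0:
        raise NonConvergenceError("every Monte Carlo refit failed")

    estimates = dict(zip(names, fit.mechanism.param_vector()))
    standard_errors = {}
    ci68, ci95, histograms = {}, {}, {}
    for j, name in enumerate(names):
        col = draws[:, j]
        if col.size < 2 or col.max() == col.min():
            # identical draws: the SE is exactly zero (np.std's mean round-off otherwise leaks in)
            standard_errors[name] = 0.0
        else:
            standard_errors[name] = float(np.std(col, ddof=1))
        ci68[name] = tuple(np.percentile(col, [16.0, 84.0]))
        ci95[name] = tuple(np.percentile(col, [2.5, 97.5]))
        histograms[name] = np.histogram(col, bins=50)
    return MonteCarloResult(
        param_names=names,
        estimates=estimates,
        standard_errors=standard_errors,
        ci68=ci68,
        ci95=ci95,
        histograms=histograms,
        draws=draws,
        n_iterations=n_iter,
        n_dropped=n_dropped,
        seed=seed,
        method=method,
        high_drop_rate=n_dropped > 0.2 * n_iter,
    )


@dataclass
class FitReport:
    """All requested mechanisms fit to one isotherm, ranked against the simplest."""

    fits: dict[str, FitResult]
    comparisons: dict[str, ModelComparison]
    errors: dict[str, str]
    monte_carlo: dict[str, MonteCarloResult]
    non_identifiable: dict[str, list[str]]
    preferred: str
    table: pd.DataFrame


#: decades of Monte-Carlo parameter spread beyond which a fit is flagged
NON_IDENTIFIABLE_DECADES = 2.0


def fit_report(
    iso: Isotherm,
    kinds: Sequence[str],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    alpha: float = 0.05,
    mc_iterations: int = 0,
    seed: int = 0,
) -> FitReport:
    """Fit several mechanisms, compare each against the simplest by F-test.

    Produces a machine-readable table (one row per mechanism, one column
    per dissociation constant, p-value against the simplest mechanism, and
    a flag on the preferred model).  The preferred model is the
    lowest-SSR mechanism among those statistically better than the simplest
    (p < alpha); otherwise the simplest.  With ``mc_iterations > 0`` a
    Monte Carlo run per mechanism flags parameters whose draw histograms
    span more than two decades as non-identifiable.
    """
    kinds = list(kinds)
    if len(kinds) < 2:
        raise ParameterDomainError("a model-comparison report needs at least 2 mechanisms")
    fits: dict[str, FitResult] = {}
    errors: dict[str, str] = {}
    for kind in kinds:
        try:
            fits[kind] = fit_isotherm(iso, kind, bounds=bounds)
        except Exception as exc:
            errors[kind] = repr(exc)
    if not fits:
        raise NonConvergenceError("no requested mechanism could be fit", diagnostics=errors)

    simplest = min(fits, key=lambda k: (fits[k].n_params, fits[k].ssr))
    comparisons: dict[str, ModelComparison] = {}
    for kind, fr in fits.items():
        if kind == simplest or fr.n_params <= fits[simplest].n_params:
            continue
        comparisons[kind] = f_test(fits[simplest], fr, alpha=alpha)

    better = [k for k, c in comparisons.items() if c.p_value < alpha]
    preferred = min(better, key=lambda k: fits[k].ssr) if better else simplest

    monte_carlo: dict[str, MonteCarloResult] = {}
    non_identifiable: dict[str, list[str]] = {}
    if mc_iterations > 0:
        for kind, fr in fits.items():
            mc = monte_carlo_errors(fr, iso, n_iter=mc_iterations, seed=seed, bounds=bounds)
            monte_carlo[kind] = mc
            wide = [n for n in mc.param_names if mc.decade_span(n) > NON_IDENTIFIABLE_DECADES]
            if wide:
                non_identifiable[kind] = wide

    all_param_names = ("K_D_D", "K_D_A", "K_D_A_D", "K_D_Aprime", "alpha")
    rows = []
    for kind in kinds:
        row: dict[str, object] = {"mechanism": kind}
        if kind in fits:
            fr = fits[kind]
            for name in all_param_names:
                row[name] = fr.params.get(name, np.nan)
            row["ssr"] = fr.ssr
            row["n_params"] = fr.n_params
            row["p_vs_simplest"] = (
                comparisons[kind].p_value if kind in comparisons else (np.nan if kind != simplest else 1.0)
            )
            row["preferred"] = kind == preferred
            row["non_identifiable"] = ";".join(non_identifiable.get(kind, []))
        else:
            row["error"] = errors[kind]
        rows.append(row)
    table = pd.DataFrame(rows)
    return FitReport(
        fits=fits,
        comparisons=comparisons,
        errors=errors,
        monte_carlo=monte_carlo,
        non_identifiable=non_identifiable,
        preferred=preferred,
        table=table,
    )
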