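"""Maximum actin assembly rates from pyrene-actin fluorescence time courses.

Pyrene-labeled actin fluoresces more strongly once incorporated into
filaments, so a polymerization time course is read out as a rising
fluorescence trace.  The trace is converted to polymerized-actin
concentration by linear normalization between the baseline and plateau
fluorescence, scaled to the polymerizable actin (total minus the critical
concentration below which filaments do not grow).  The maximum assembly
rate is the largest ordinary-least-squares slope over all contiguous
windows of fixed width — a deliberately transparent estimator with no
splines or smoothing, whose bias for a smooth trace is bounded by the
third-derivative term (window_width^2 * |P'''| / 24).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterDomainError, UnsaturatedTraceError

__all__ = [
    "PyreneTrace",
    "PolymerSeries",
    "RateEstimate",
    "to_polymer",
    "max_assembly_rate",
    "titration_rates",
]

DEFAULT_CRITICAL_CONC = 0.1  # uM; barbed-end critical concentration of actin
TAIL_FRACTION = 0.05  # fraction of points averaged for baseline / plateau
PLATEAU_NOISE_MULTIPLE = 5.0
MIN_SAMPLES = 50


@dataclass
class PyreneTrace:
    """One fluorescence time course with its assay composition.

    ``actin_total`` in uM (assays here use 4 uM actin, 5% pyrene-labeled);
    ``critical_conc`` is the non-polymerizable monomer pool.
    """

    time: np.ndarray  # s, strictly increasing
    fluorescence: np.ndarray  # AU
    actin_total: float = 4.0
    pyrene_fraction: float = 0.05
    critical_conc: float = DEFAULT_CRITICAL_CONC
    label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape or self.time.ndim != 1:
            raise ParameterDomainError("time and fluorescence must be 1-D arrays of equal length")
        if self.time.size < MIN_SAMPLES:
            raise ParameterDomainError(f"a trace needs at least {MIN_SAMPLES} samples")
        if np.any(np.diff(self.time) <= 0):
            raise ParameterDomainError("time must be strictly increasing")
        if not self.actin_total > self.critical_conc:
            raise ParameterDomainError("actin_total must exceed the critical concentration")
        if not 0 < self.pyrene_fraction <= 1:
            raise ParameterDomainError("pyrene_fraction must be in (0, 1]")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class PolymerSeries:
    """Polymerized actin (uM) vs time, with the normalization anchors."""

    time: np.ndarray
    polymer: np.ndarray  # uM
    baseline: float  # F0, AU
    plateau: float  # Finf, AU


@dataclass
class RateEstimate:
    """Maximum windowed-OLS assembly rate and where it was found."""

    max_rate: float  # nM/s
    window_start: float  # s
    window_end: float  # s
    window_points: int
    baseline: float  # AU
    plateau: float  # AU

    def to_dict(self) -> dict:
        return {
            "max_rate_nM_per_s": self.max_rate,
            "window_start_s": self.window_start,
            "window_end_s": self.window_end,
            "window_points": self.window_points,
            "baseline_au": self.baseline,
            "plateau_au": self.plateau,
        }


def _tail_means(values: np.ndarray) -> tuple[float, float, float]:
    """Baseline, plateau, and baseline noise sd from the 5% tails."""
    k = max(1, int(round(TAIL_FRACTION * values.size)))
    head = values[:k]
    tail = values[-k:]
    return float(head.mean()), float(tail.mean()), float(head.std())


def to_polymer(trace: PyreneTrace, plateau: float | None = None) -> PolymerSeries:
    """Convert fluorescence to polymerized-actin concentration.

    P(t) = (F(t) - F0) / (Finf - F0) * (actin_total - critical_conc), with
    F0 the mean of the first 5% of points and Finf the mean of the last 5%
    (or the supplied ``plateau``).  A trace whose plateau rise is below five
    baseline noise standard deviations is rejected as unsaturated unless a
    plateau is supplied; a perfectly flat trace maps to zero polymer.
    """
    f = trace.fluorescence
    f0, f_inf_est, noise_sd = _tail_means(f)
    if plateau is None:
        f_inf = f_inf_est
        rise = f_inf - f0
        if rise == 0.0:
            return PolymerSeries(trace.time, np.zeros_like(f), f0, f_inf)
        if rise < PLATEAU_NOISE_MULTIPLE * noise_sd or rise < 0:
            raise UnsaturatedTraceError(
                "trace does not reach a plateau "
                f"(rise {rise:.3g} AU vs baseline noise sd {noise_sd:.3g} AU); "
                "supply plateau= explicitly"
            )
    else:
        f_inf = float(plateau)
        if f_inf <= f0:
            raise ParameterDomainError("supplied plateau must exceed the baseline")
    scale = (trace.actin_total - trace.critical_conc) / (f_inf - f0)
    return PolymerSeries(trace.time, (f - f0) * scale, f0, f_inf)


def _default_window(n: int) -> int:
    k = max(11, int(round(0.05 * n)))
    if k % 2 == 0:
        k += 1
    return min(k, n // 2 if (n // 2) % 2 == 1 else n // 2 - 1)


def _window_slopes(t: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """OLS slope of y on t in every contiguous window of k points."""
    tw = np.lib.stride_tricks.sliding_window_view(t, k)
    yw = np.lib.stride_tricks.sliding_window_view(y, k)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    dt = tw - tm
    return np.sum(dt * (yw - ym), axis=1) / np.sum(dt * dt, axis=1)


def max_assembly_rate(series: PolymerSeries, window_points: int | None = None) -> RateEstimate:
    """Largest windowed OLS slope of the polymer series, in nM/s.

    ``window_points`` must be odd, at least 5, and at most half the trace
    (default 5% of the trace, minimum 11).  The slope (uM/s) of the best
    window is scaled by 1000 to nM/s; a trace that only depolymerizes
    reports a rate of 0.
    """
    n = series.time.size
    if window_points is None:
        window_points = _default_window(n)
    k = int(window_points)
    if k % 2 == 0 or k < 5 or k > n // 2:
        raise ParameterDomainError(
            f"window_points must be odd, >= 5 and <= n/2 = {n // 2}, got {k}"
        )
    slopes = _window_slopes(series.time, series.polymer, k)
    i = int(np.argmax(slopes))
    return RateEstimate(
        max_rate=max(float(slopes[i]), 0.0) * 1e3,
        window_start=float(series.time[i]),
        window_end=float(series.time[i + k - 1]),
        window_points=k,
        baseline=series.baseline,
        plateau=series.plateau,
    )


def titration_rates(
    traces: Sequence[tuple[float, PyreneTrace]],
    window_points: int | None = None,
) -> pd.DataFrame:
    """Per-trace maximum assembly rates for a dose series.

    ``traces`` are (activator concentration uM, trace) pairs.  Traces that
    fail conversion or rate extraction contribute a row with the error
    message instead of aborting the whole titration.
    """
    rows = []
    for conc, trace in traces:
        row = {"activator_uM": float(conc), "max_rate_nM_per_s": np.nan, "error": ""}
        try:
            est = max_assembly_rate(to_polymer(trace), window_points=window_points)
            row["max_rate_nM_per_s"] = est.max_rate
            row["window_start_s"] = est.window_start
            row["window_end_s"] = est.window_end
        except Exception as exc:
            row["error"] = repr(exc)
        rows.append(row)
    return pd.DataFrame(rows, columns=["activator_uM", "max_rate_nM_per_s", "window_start_s", "window_end_s", "error"])
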