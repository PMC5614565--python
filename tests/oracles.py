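"""Independent brute-force oracles for the equilibrium solvers and estimators.

These deliberately share no code with the package: equilibria are solved by
nested bisection directly on the raw mass-action and conservation
equations (an inner bisection for free receptor at fixed free ligand, an
outer bisection on the remaining conservation residual), plus a damped
fixed-point iteration for the single-site case.  Statistical oracles
(grid-search minimizer, F-tail by numerical integration of the density)
are equally pedestrian on purpose.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad
from scipy.special import gammaln


def _bisect(f, lo, hi, iters):
    flo = f(lo)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if (f(mid) > 0) == (flo > 0):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _species_two_site(kind, params, w, r):
    """Raw mass-action complex concentrations at free (W, R) = (w, r)."""
    if kind == "single_site":
        return {"WR": w * r / params["K_D_D"]}
    if kind == "sequential_two_site":
        wr_d = w * r / params["K_D_D"]
        return {"WR_D": wr_d, "WR_DA": wr_d * r / params["K_D_A_D"]}
    if kind == "cyclic_two_site":
        wr_d = w * r / params["K_D_D"]
        wr_a = w * r / params["K_D_A"]
        return {
            "WR_D": wr_d,
            "WR_A": wr_a,
            "WR_DA": params["alpha"] * w * r * r / (params["K_D_D"] * params["K_D_A"]),
        }
    raise ValueError(kind)


_RAC = {"WR": 1, "WR_D": 1, "WR_A": 1, "WR_DA": 2}
_WRC = {"WR": 1, "WR_D": 1, "WR_A": 1, "WR_DA": 1}


def oracle_solve(kind, params, w_tot, r_tot, outer_iters=200, inner_iters=100):
    """Nested-bisection equilibrium; returns (free_receptor, free_ligand, species).

    For the GST-dimer mechanism the outer variable is free WRC and
    free_ligand is the free GST dimer.
    """
    if kind == "gst_dimer":
        g2_tot = r_tot / 2.0
        kda, kdap = params["K_D_A"], params["K_D_Aprime"]

        def g2_at(w):
            if g2_tot == 0:
                return 0.0
            return _bisect(
                lambda g2: g2 * (1.0 + w / kda + w * w / (kda * kdap)) - g2_tot,
                0.0,
                g2_tot,
                inner_iters,
            )

        def wrc_residual(w):
            g2 = g2_at(w)
            return w + g2 * (w / kda + 2.0 * w * w / (kda * kdap)) - w_tot

        w = 0.0 if w_tot == 0 else _bisect(wrc_residual, 0.0, w_tot, outer_iters)
        g2 = g2_at(w)
        return w, g2, {"G2W": g2 * w / kda, "G2W2": g2 * w * w / (kda * kdap)}

    def w_at(r):
        if w_tot == 0:
            return 0.0
        return _bisect(
            lambda w: w + sum(_WRC[k] * v for k, v in _species_two_site(kind, params, w, r).items()) - w_tot,
            0.0,
            w_tot,
            inner_iters,
        )

    def ligand_residual(r):
        w = w_at(r)
        return r + sum(_RAC[k] * v for k, v in _species_two_site(kind, params, w, r).items()) - r_tot

    r = 0.0 if r_tot == 0 else _bisect(ligand_residual, 0.0, r_tot, outer_iters)
    w = w_at(r)
    return w, r, _species_two_site(kind, params, w, r)


def oracle_fraction_unbound(kind, params, w_tot, r_tot):
    w, _, _ = oracle_solve(kind, params, w_tot, r_tot)
    return w / w_tot


def fixed_point_single_site(w_tot, r_tot, kd, damping=0.05, iters=1_000_000):
    """Damped fixed-point iteration on [WR] = (W_tot-[WR])(R_tot-[WR])/kd."""
    wr = 0.0
    for _ in range(iters):
        wr = (1.0 - damping) * wr + damping * (w_tot - wr) * (r_tot - wr) / kd
    return wr


def grid_search_single_site_log10kd(ligand_total, receptor_total, observed, lo=-3.0, hi=3.0, step=1e-3):
    """Exhaustive SSR minimizer over log10 K_D for the single-site model."""
    grid = np.arange(lo, hi + step / 2, step)
    kd = 10.0 ** grid[:, None]
    w = np.asarray(receptor_total, dtype=float)[None, :]
    r = np.asarray(ligand_total, dtype=float)[None, :]
    b = w + r + kd
    wr = 2.0 * w * r / (b + np.sqrt(b * b - 4.0 * w * r))
    frac = (w - wr) / w
    ssr = np.sum((np.asarray(observed)[None, :] - frac) ** 2, axis=1)
    return float(grid[int(np.argmin(ssr))])


def f_upper_tail_by_quadrature(x, d1, d2):
    """P(F > x) for the F(d1, d2) distribution by integrating its density."""

    def density(t):
        logc = (
            0.5 * d1 * math.log(d1 / d2)
            + gammaln((d1 + d2) / 2.0)
            - gammaln(d1 / 2.0)
            - gammaln(d2 / 2.0)
        )
        return math.exp(
            logc + (d1 / 2.0 - 1.0) * math.log(t) - ((d1 + d2) / 2.0) * math.log1p(d1 * t / d2)
        )

    value, _ = quad(density, x, np.inf, limit=200)
    return value


def windowed_slopes_bruteforce(t, y, k):
    """Per-window OLS slope by np.polyfit, one window at a time."""
    return np.array([np.polyfit(t[i : i + k], y[i : i + k], 1)[0] for i in range(len(t) - k + 1)])
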