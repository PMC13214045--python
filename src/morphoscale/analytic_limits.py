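"""Closed-form limiting solutions and gradient-shape classification.

Two limiting regimes of the morphogen-expander system have simple profile
families: a spatially uniform expander gives the classical exponential
gradient of a source-diffusion-degradation (SDD) system with a constant
effective degradation rate, while a strongly position-dependent expander
produces gradients that are better described by a power law.  This module
provides the exact constant-rate SDD solution (used as an independent
oracle for the numerical solver), least-squares classification of a
computed gradient as exponential versus power-law, and the no-feedback
analytic baseline profiles for the scaling and robustness metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .model_core import ProfileSet, SpatialGrid

__all__ = [
    "ShapeFit",
    "sdd_steady_profile",
    "fit_gradient_shape",
    "baseline_scaling_profile",
    "baseline_robustness_profile",
]


@dataclass
class ShapeFit:
    """Result of fitting a gradient with exponential and power-law forms.

    Both fits are least squares on log-concentration.  ``preference`` is
    the signed score ``(rss_exp - rss_pl) / (rss_exp + rss_pl)`` in
    [-1, 1]: positive means the power law fits better.
    """

    lambda_exp: float
    amp_exp: float
    alpha_pl: float
    offset_pl: float
    rss_exp: float
    rss_pl: float
    preference: float


def sdd_steady_profile(
    D: float,
    K: float,
    nu: float,
    wM: float,
    L: float,
    grid: SpatialGrid | np.ndarray,
) -> np.ndarray:
    """Exact steady state of ``D C'' - K C + nu * theta(wM - x) = 0``.

    Zero-flux boundaries at 0 and L.  The solution is piecewise
    hyperbolic-cosine with decay length ``lambda = sqrt(D/K)``::

        C(x) = nu/K + A cosh(x/lambda)        for x <  wM
        C(x) = B cosh((L - x)/lambda)         for x >= wM

    with A, B fixed by continuity of value and derivative at wM.
    """
    if not (D > 0 and K > 0 and nu >= 0 and L > 0):
        raise ValueError("D, K, L must be positive and nu nonnegative")
    if not (0 < wM < L):
        raise ValueError(f"source width must satisfy 0 < wM < L, got wM={wM}, L={L}")
    x = grid.positions if isinstance(grid, SpatialGrid) else np.asarray(grid, float)
    lam = np.sqrt(D / K)
    sL = np.sinh(L / lam)
    A = -(nu / K) * np.sinh((L - wM) / lam) / sL
    B = (nu / K) * np.sinh(wM / lam) / sL
    return np.where(
        x < wM,
        nu / K + A * np.cosh(x / lam),
        B * np.cosh((L - x) / lam),
    )


def _fit_window(
    profile: ProfileSet, fit_region: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    r = profile.grid.r
    lo, hi = fit_region
    mask = (r >= lo) & (r <= hi)
    if int(mask.sum()) < 5:
        raise ValueError(f"fewer than 5 nodes in fit region {fit_region}")
    M = profile.M[mask]
    if np.any(M <= 0):
        raise ValueError("morphogen must be strictly positive on the fit region")
    return profile.grid.positions[mask], M


def fit_gradient_shape(
    profile: ProfileSet,
    fit_region: tuple[float, float] = (0.15, 0.95),
) -> ShapeFit:
    """Classify a morphogen gradient as exponential versus power-law.

    Fits ``A exp(-x/lambda)`` (linear least squares of log M on x) and
    ``B (x + c)^(-alpha)`` (linear fit of log M on log(x + c), with the
    offset c found by a bounded 1D search) over the relative-position
    window ``fit_region``, and reports which family describes the profile
    better.  The default window excludes the morphogen source and the
    far-boundary plateau.
    """
    x, M = _fit_window(profile, fit_region)
    logM = np.log(M)
    L = profile.grid.L

    # exponential: log M = log A - x / lambda
    slope, intercept = np.polyfit(x, logM, 1)
    rss_exp = float(np.sum((intercept + slope * x - logM) ** 2))
    lambda_exp = -1.0 / slope if slope < 0 else np.inf
    amp_exp = float(np.exp(intercept))

    # power law: log M = log B - alpha log(x + c); nested search over c
    def rss_for(log_c: float) -> float:
        c = np.exp(log_c)
        lx = np.log(x + c)
        a, b = np.polyfit(lx, logM, 1)
        return float(np.sum((b + a * lx - logM) ** 2))

    res = minimize_scalar(
        rss_for,
        bounds=(np.log(1e-6 * L), np.log(10.0 * L)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    c = float(np.exp(res.x))
    lx = np.log(x + c)
    a, b = np.polyfit(lx, logM, 1)
    rss_pl = float(np.sum((b + a * lx - logM) ** 2))
    alpha_pl = -a

    denom = rss_exp + rss_pl
    preference = (rss_exp - rss_pl) / denom if denom > 0 else 0.0
    return ShapeFit(
        lambda_exp=float(lambda_exp),
        amp_exp=amp_exp,
        alpha_pl=float(alpha_pl),
        offset_pl=c,
        rss_exp=rss_exp,
        rss_pl=rss_pl,
        preference=float(preference),
    )


def baseline_scaling_profile(
    lambda_rel: float, length_ratio: float, r_values: np.ndarray
) -> np.ndarray:
    """Scaling profile of a fixed exponential gradient under length change.

    With no morphogen-expander feedback the gradient shape and amplitude
    are unchanged by tissue length, so the concentration found at relative
    position r in the small tissue sits at absolute position ``r * L1``,
    i.e. relative position ``rho = r / length_ratio`` in the large tissue:
    ``S_M(r) = 1 - r (1 - 1/length_ratio)``.
    """
    if not lambda_rel > 0:
        raise ValueError("lambda_rel must be positive")
    if not length_ratio > 1:
        raise ValueError("length_ratio must exceed 1")
    r = np.asarray(r_values, dtype=float)
    rho = np.clip(r / length_ratio, 0.0, 1.0)
    return 1.0 - np.abs(rho - r)


def baseline_robustness_profile(
    lambda_rel: float, factor: float, r_values: np.ndarray
) -> np.ndarray:
    """Robustness profile of an exponential gradient to amplitude fold change.

    Scaling the amplitude of ``exp(-x/lambda)`` by ``factor`` (and
    ``1/factor``) shifts every concentration threshold by
    ``+-(lambda/L) ln(factor)`` in relative coordinates; the shifted
    positions are clamped to [0, 1] before averaging.
    """
    if not lambda_rel > 0:
        raise ValueError("lambda_rel must be positive")
    if not factor > 1:
        raise ValueError("factor must exceed 1")
    r = np.asarray(r_values, dtype=float)
    shift = lambda_rel * np.log(factor)
    rho_plus = np.clip(r + shift, 0.0, 1.0)
    rho_minus = np.clip(r - shift, 0.0, 1.0)
    return 1.0 - 0.5 * (np.abs(rho_plus - r) + np.abs(rho_minus - r))
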