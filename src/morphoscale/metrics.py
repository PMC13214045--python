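"""Position-dependent patterning metrics.

All three metrics read a gene-expression boundary as the position where
the morphogen concentration crosses a threshold, and quantify how much
that position moves (or jitters) in relative coordinates r = x/L:

* scaling ``S_M(r) = 1 - |rho_L - r|`` — shift of the position carrying
  the concentration M(r; L1) when the tissue grows from L1 to L2;
* robustness ``R_M(r) = 1 - (|rho_+ - r| + |rho_- - r|) / 2`` — mean shift
  under fold changes of the morphogen production rate;
* precision ``P_M(r) = 1 - sigma_r(r)`` with
  ``sigma_r = sqrt(M / (d (dM/dr)^2))`` — predicted positional standard
  deviation of a boundary given concentration-readout noise, where ``d``
  is an effective cell size linking concentration variance to the mean.

Threshold positions are recovered by monotone log-linear interpolation of
the profiles; positions falling outside the tissue are clamped to [0, 1]
and flagged, which keeps the metrics defined tissue-wide (profiles that
plateau otherwise make the inversion diverge).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelParams, ProfileSet

__all__ = [
    "MetricProfile",
    "ExpanderSummary",
    "PatterningClassification",
    "MonotonicityError",
    "invert_profile",
    "scaling_profile",
    "robustness_profile",
    "precision_profile",
    "expander_summaries",
    "classify_scaling",
    "useful_patterning_region",
    "default_r_grid",
]


class MonotonicityError(ValueError):
    """Profile is not monotonically non-increasing where inversion needs it."""


@dataclass
class MetricProfile:
    """A metric evaluated on a grid of relative positions.

    ``clamped`` flags positions where a boundary clamp (or, for precision,
    a divergent zero-slope sentinel) was applied.  For the precision
    metric ``sigma`` retains the raw positional standard deviation before
    the values are floored at zero (NaN where divergent).
    """

    r_values: np.ndarray
    values: np.ndarray
    clamped: np.ndarray
    sigma: np.ndarray | None = None

    def at(self, r: float) -> float:
        return float(np.interp(r, self.r_values, self.values))


@dataclass
class ExpanderSummary:
    """Scalar descriptors of an expander profile.

    ``f_E`` is the dynamic range (0 = uniform, 1 = fully position
    dependent); ``lambda_E`` the half-decay length measured from the far
    tissue edge (None when the expander never falls to half its edge
    value); ``w_E`` the expander source width (integral of the repressive
    Hill term); ``mu_bar`` the spatially integrated effective expander
    degradation rate.
    """

    f_E: float | None
    lambda_E: float | None
    w_E: float
    mu_bar: float


@dataclass
class PatterningClassification:
    """Scaling class of a system plus its useful-patterning intervals."""

    kind: str  # "none" | "local" | "global"
    local_position: float | None = None
    useful_intervals: list[tuple[float, float]] = field(default_factory=list)


def default_r_grid(n: int = 101) -> np.ndarray:
    return np.linspace(0.0, 1.0, n)


# ---------------------------------------------------------------------------
# Profile inversion
# ---------------------------------------------------------------------------

def _monotone_branch(
    r: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Search region for inversion: from the profile maximum rightward.

    Gradients read out by target-tissue cells decay away from the source;
    a profile may dip right at x = 0 (where the expander minimum maximizes
    morphogen degradation), so the searchable branch starts at the global
    maximum.  A rise *after* the maximum is a genuine violation.
    """
    i0 = int(np.argmax(values))
    rb, vb = r[i0:], values[i0:]
    scale = np.max(np.abs(values)) + 1e-300
    rises = np.diff(vb) > 1e-9 * scale
    if np.any(rises):
        i = int(np.argmax(rises))
        raise MonotonicityError(
            f"profile increases at r={rb[i]:.4g} -> r={rb[i + 1]:.4g} "
            f"({vb[i]:.6g} -> {vb[i + 1]:.6g})"
        )
    return rb, vb


def invert_profile(
    r: np.ndarray, values: np.ndarray, c: float, check: bool = True
) -> tuple[float, bool]:
    """Smallest relative position where the profile equals ``c``.

    The profile must be monotonically non-increasing on the search region,
    which runs from its global maximum to the far edge.  Interpolation is
    log-linear in concentration (exact for exponential decay); cells
    containing non-positive values fall back to linear.  Returns
    ``(rho, clamped)``: concentrations above the profile maximum clamp to
    rho=0, below the minimum to rho=1, with the flag set.
    """
    r = np.asarray(r, dtype=float)
    values = np.asarray(values, dtype=float)
    if check:
        r, values = _monotone_branch(r, values)
    else:
        i0 = int(np.argmax(values))
        r, values = r[i0:], values[i0:]
    if c > values[0]:
        return 0.0, True
    if c == values[0]:
        return float(r[0]), False
    if c < values[-1]:
        return 1.0, True
    # monotone non-increasing: first index with values[i] <= c
    i = int(np.argmax(values <= c))
    v_hi, v_lo = values[i - 1], values[i]
    if v_hi == v_lo:
        return float(r[i - 1]), False
    if v_lo > 0 and c > 0:
        frac = (np.log(v_hi) - np.log(c)) / (np.log(v_hi) - np.log(v_lo))
    else:
        frac = (v_hi - c) / (v_hi - v_lo)
    return float(r[i - 1] + frac * (r[i] - r[i - 1])), False


def _eval_profile(r_grid: np.ndarray, values: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Log-linear interpolation of a positive profile (linear fallback)."""
    if np.all(values > 0):
        return np.exp(np.interp(r, r_grid, np.log(values)))
    return np.interp(r, r_grid, values)


# ---------------------------------------------------------------------------
# Metric profiles
# ---------------------------------------------------------------------------

def scaling_profile(
    ps1: ProfileSet,
    ps2: ProfileSet,
    r_values: np.ndarray | None = None,
) -> MetricProfile:
    """Scaling S_M(r) from profiles at two tissue lengths (L2 > L1).

    Absolute (not normalized) concentrations are compared: for each r the
    concentration M(r; L1) is located in the larger system at relative
    position rho_L, and S_M(r) = 1 - |rho_L - r|.
    """
    if not (ps1.converged and ps2.converged):
        raise ValueError("both profiles must be converged")
    if not ps2.grid.L > ps1.grid.L:
        raise ValueError("second profile must be at the larger tissue length")
    r_values = default_r_grid() if r_values is None else np.asarray(r_values, float)
    _monotone_branch(ps2.grid.r, ps2.M)
    M1 = _eval_profile(ps1.grid.r, ps1.M, r_values)
    vals = np.empty_like(r_values)
    clamped = np.zeros_like(r_values, dtype=bool)
    for j, (r, c) in enumerate(zip(r_values, M1)):
        rho, fl = invert_profile(ps2.grid.r, ps2.M, c, check=False)
        vals[j] = 1.0 - abs(rho - r)
        clamped[j] = fl
    return MetricProfile(r_values, vals, clamped)


def robustness_profile(
    base: ProfileSet,
    plus: ProfileSet,
    minus: ProfileSet,
    r_values: np.ndarray | None = None,
) -> MetricProfile:
    """Robustness R_M(r) to paired production-rate perturbations.

    ``plus`` and ``minus`` are steady profiles at the same tissue length
    with the perturbed rates; R_M(r) averages the positional shifts of the
    base concentration M(r) in the two perturbed systems.
    """
    for ps in (base, plus, minus):
        if not ps.converged:
            raise ValueError("all profiles must be converged")
    if not (base.grid.L == plus.grid.L == minus.grid.L):
        raise ValueError("profiles must share the tissue length")
    r_values = default_r_grid() if r_values is None else np.asarray(r_values, float)
    _monotone_branch(plus.grid.r, plus.M)
    _monotone_branch(minus.grid.r, minus.M)
    Mb = _eval_profile(base.grid.r, base.M, r_values)
    vals = np.empty_like(r_values)
    clamped = np.zeros_like(r_values, dtype=bool)
    for j, (r, c) in enumerate(zip(r_values, Mb)):
        rho_p, fp = invert_profile(plus.grid.r, plus.M, c, check=False)
        rho_m, fm = invert_profile(minus.grid.r, minus.M, c, check=False)
        vals[j] = 1.0 - 0.5 * (abs(rho_p - r) + abs(rho_m - r))
        clamped[j] = fp or fm
    return MetricProfile(r_values, vals, clamped)


def precision_profile(
    ps: ProfileSet,
    d: float,
    r_values: np.ndarray | None = None,
) -> MetricProfile:
    """Precision P_M(r) = 1 - sigma_r(r) for readout noise of scale ``d``.

    ``sigma_r = sqrt(M(r) / (d (dM/dr)^2))`` with the slope taken by
    central differences in relative coordinates.  Zero-slope (plateau)
    positions get sigma = NaN and P = 0 with the flag set; elsewhere P is
    floored at 0 while the raw sigma is retained.
    """
    if not ps.converged:
        raise ValueError("profile must be converged")
    if not d > 0:
        raise ValueError("cell size d must be positive")
    r_values = default_r_grid() if r_values is None else np.asarray(r_values, float)
    rg = ps.grid.r
    M = ps.M
    dMdr = np.gradient(M, rg)
    Mq = np.interp(r_values, rg, M)
    slope = np.interp(r_values, rg, dMdr)
    tiny = 1e-12 * np.max(np.abs(M))
    divergent = np.abs(slope) < tiny
    sigma = np.full_like(r_values, np.nan)
    ok = ~divergent
    sigma[ok] = np.sqrt(np.maximum(Mq[ok], 0.0) / (d * slope[ok] ** 2))
    vals = np.where(divergent, 0.0, np.maximum(1.0 - sigma, 0.0))
    return MetricProfile(r_values, vals, divergent, sigma=sigma)


# ---------------------------------------------------------------------------
# Expander summaries
# ---------------------------------------------------------------------------

def expander_summaries(ps: ProfileSet, p: ModelParams) -> ExpanderSummary:
    """Dynamic range, half-decay length, source width and mean degradation.

    f_E = (E(L) - E(w_M)) / E(L) (None when E(L) = 0);
    w_E = integral of m^h / (m^h + M^h) over the tissue;
    mu_bar = integral of mu / (1 + E/zeta);
    lambda_E = L - x_half where x_half is the largest position at which E
    crosses E(L)/2 (log-linear interpolation), None when E never falls to
    half its edge value.
    """
    if not ps.converged:
        raise ValueError("profile must be converged")
    grid = ps.grid
    x = grid.positions
    E = ps.E
    M = ps.M
    EL = float(E[-1])
    wM = p.w_M
    if EL > 0:
        EwM = float(np.interp(wM, x, E))
        f_E = (EL - EwM) / EL
    else:
        f_E = None

    with np.errstate(over="ignore"):
        hill = 1.0 / (1.0 + (np.maximum(M, 0.0) / p.m) ** p.h)
    w_E = float(np.trapezoid(hill, x))
    mu_bar = float(np.trapezoid(p.mu / (1.0 + E / p.zeta), x))

    lambda_E = None
    if EL > 0:
        half = 0.5 * EL
        below = E <= half
        if np.any(below):
            i = int(np.nonzero(below)[0][-1])  # largest x with E <= half
            if i == grid.Nx - 1:
                lambda_E = 0.0
            else:
                e_lo, e_hi = E[i], E[i + 1]
                if e_lo > 0:
                    frac = (np.log(half) - np.log(e_lo)) / (np.log(e_hi) - np.log(e_lo))
                else:
                    frac = (half - e_lo) / (e_hi - e_lo)
                x_half = x[i] + frac * (x[i + 1] - x[i])
                lambda_E = float(grid.L - x_half)
    return ExpanderSummary(f_E=f_E, lambda_E=lambda_E, w_E=w_E, mu_bar=mu_bar)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_scaling(
    S: MetricProfile,
    high_threshold: float = 0.98,
    target_region: tuple[float, float] = (0.1, 1.0),
) -> PatterningClassification:
    """Classify a scaling profile as global, local, or neither.

    Global: S exceeds the threshold at every evaluated position of the
    target tissue.  Local: the threshold is exceeded somewhere but not
    everywhere; ``local_position`` is the argmax of S.  None otherwise.
    """
    lo, hi = target_region
    mask = (S.r_values >= lo) & (S.r_values <= hi)
    if not np.any(mask):
        raise ValueError(f"empty target region {target_region}")
    vals = S.values[mask]
    rs = S.r_values[mask]
    high = vals >= high_threshold
    if np.all(high):
        return PatterningClassification(kind="global")
    if np.any(high):
        return PatterningClassification(
            kind="local", local_position=float(rs[int(np.argmax(vals))])
        )
    return PatterningClassification(kind="none")


def useful_patterning_region(
    S: MetricProfile,
    R: MetricProfile,
    P: MetricProfile,
    threshold: float = 0.95,
) -> list[tuple[float, float]]:
    """Maximal r-intervals where scaling, robustness and precision all
    exceed ``threshold``; interval endpoints are interpolated crossings of
    min(S, R, P)."""
    r = S.r_values
    if not (np.array_equal(r, R.r_values) and np.array_equal(r, P.r_values)):
        raise ValueError("metric profiles must share the r-grid")
    m = np.minimum(np.minimum(S.values, R.values), P.values)
    above = m > threshold
    intervals: list[tuple[float, float]] = []
    i = 0
    n = len(r)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        start = r[i]
        if i > 0 and m[i] != m[i - 1]:
            start = r[i - 1] + (threshold - m[i - 1]) / (m[i] - m[i - 1]) * (r[i] - r[i - 1])
        end = r[j]
        if j + 1 < n and m[j] != m[j + 1]:
            end = r[j] + (m[j] - threshold) / (m[j] - m[j + 1]) * (r[j + 1] - r[j])
        intervals.append((float(start), float(end)))
        i = j + 1
    return intervals
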