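"""Method-of-lines integration of the morphogen-expander system.

The PDEs are discretized on a uniform grid with second-order central
differences and zero-flux (reflecting) boundaries, giving a stiff ODE
system in the interleaved state vector ``y = (M_0, E_0, M_1, E_1, ...)``.
Interleaving keeps the Jacobian banded with bandwidth 2 (diffusion couples
neighbouring nodes of one species, the reaction terms couple M and E at the
same node), so implicit steps cost O(Nx) via a banded LU solve.

Steady states are found by pseudo-transient continuation: backward-Euler
steps with a geometrically growing time step (each step solved by Newton
iteration on the banded system), followed by an optional Newton polish of
the steady-state equations themselves.  Time-accurate transients — needed
for relaxation timing after a production-rate perturbation — use scipy's
adaptive BDF integrator with the analytic sparse Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp
from scipy.linalg import solve_banded

from .model_core import (
    ModelParams,
    ProfileSet,
    SpatialGrid,
    hill_repression,
    reaction_terms,
    source_fraction,
    validate_params,
)

__all__ = [
    "SolverOptions",
    "RelaxationResult",
    "Trajectory",
    "assemble_rhs",
    "solve_steady_state",
    "simulate_transient",
    "relax_after_perturbation",
    "mass_balance_residual",
]


@dataclass
class SolverOptions:
    """Numerical options shared by the steady-state and transient solvers.

    ``ss_tol`` is the steady-state criterion: the solver declares
    convergence when ``max|dM/dt| / (max M + atol) < ss_tol`` and the same
    holds for E.  ``ss_tol_transient`` is the looser threshold used when
    timing relaxation of a BDF trajectory, whose pointwise residual floor
    is set by the integrator tolerances rather than by Newton iteration.
    """

    Nx: int = 1001
    rtol: float = 1e-8
    atol: float = 1e-10
    ss_tol: float = 1e-8
    ss_tol_transient: float = 1e-6
    t_max: float | None = None
    check_interval: float | None = None
    max_steps: int = 2000
    overflow: float = 1e12
    newton_polish: bool = True

    def __post_init__(self) -> None:
        if self.Nx < 51:
            raise ValueError(f"Nx must be >= 51, got {self.Nx}")
        for name in ("rtol", "atol", "ss_tol", "ss_tol_transient"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Trajectory:
    """Time-stamped sequence of concentration snapshots."""

    grid: SpatialGrid
    times: np.ndarray
    M: np.ndarray  # shape (n_times, Nx)
    E: np.ndarray

    def __len__(self) -> int:
        return len(self.times)

    def profile(self, i: int) -> ProfileSet:
        return ProfileSet(self.grid, self.M[i].copy(), self.E[i].copy(),
                          converged=False, t_elapsed=float(self.times[i]))

    def total_morphogen(self) -> np.ndarray:
        """Spatially integrated morphogen per snapshot (trapezoid)."""
        w = self.grid.node_weights
        return self.M @ w


@dataclass
class RelaxationResult:
    """Timing of relaxation back to steady state after a perturbation.

    ``t_max_total`` is the time at which the spatially integrated morphogen
    is extremal (maximal after a production increase, minimal after a
    decrease); ``t_ss`` is when the steady-state criterion holds, measured
    from the perturbation; ``tau_delta`` equals ``t_ss`` by convention.
    """

    tau_delta: float
    t_max_total: float
    t_ss: float
    final: ProfileSet
    converged: bool = True


# ---------------------------------------------------------------------------
# Right-hand side and Jacobian
# ---------------------------------------------------------------------------

def assemble_rhs(
    p: ModelParams, grid: SpatialGrid, M: np.ndarray, E: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (dM/dt, dE/dt) with zero-flux boundaries.

    Boundary nodes use ghost-node reflection; in boundary_flux mode the
    input flux j0 enters the x=0 control volume (width dx/2) of M.
    """
    M = np.asarray(M, dtype=float)
    E = np.asarray(E, dtype=float)
    if not (np.all(np.isfinite(M)) and np.all(np.isfinite(E))):
        raise ValueError("non-finite values in concentration arrays")
    terms = reaction_terms(p, grid, M, E)
    dM = _laplacian(M, grid.dx) * p.DM + terms.prod_M - terms.deg_M
    dE = _laplacian(E, grid.dx) * p.DE + terms.prod_E - terms.deg_E
    if p.source_mode == "boundary_flux" and p.j0:
        dM[0] += 2.0 * p.j0 / grid.dx
    return dM, dE


def _laplacian(y: np.ndarray, dx: float) -> np.ndarray:
    out = np.empty_like(y)
    out[1:-1] = y[:-2] - 2.0 * y[1:-1] + y[2:]
    out[0] = 2.0 * (y[1] - y[0])
    out[-1] = 2.0 * (y[-2] - y[-1])
    return out / dx**2


def _rhs_vec(p: ModelParams, grid: SpatialGrid, y: np.ndarray) -> np.ndarray:
    dM, dE = assemble_rhs(p, grid, y[0::2], y[1::2])
    out = np.empty_like(y)
    out[0::2] = dM
    out[1::2] = dE
    return out


def _jac_banded(p: ModelParams, grid: SpatialGrid, y: np.ndarray) -> np.ndarray:
    """Analytic Jacobian in LAPACK banded storage, bandwidth (2, 2).

    ab[u + i - j, j] = J[i, j] with u = 2, for the interleaved state.
    """
    N = grid.Nx
    n2 = 2 * N
    dx2 = grid.dx**2
    cM = p.DM / dx2
    cE = p.DE / dx2
    M = y[0::2]
    E = y[1::2]

    fx = 1.0 + E / p.xi
    fz = 1.0 + E / p.zeta
    ab = np.zeros((5, n2))

    # diagonal
    ab[2, 0::2] = -2.0 * cM - p.k / fx
    ab[2, 1::2] = -2.0 * cE - p.mu / fz**2

    # diffusion neighbours (same species, offset +-2)
    ab[0, 2::2] = cM          # J[2n, 2n+2], n = 0..N-2
    ab[0, 2] = 2.0 * cM       # reflecting boundary at node 0
    ab[0, 3::2] = cE
    ab[0, 3] = 2.0 * cE
    ab[4, 0:n2 - 2:2] = cM    # J[2n, 2n-2] stored at column 2n-2
    ab[4, n2 - 4] = 2.0 * cM  # reflecting boundary at node N-1
    ab[4, 1:n2 - 2:2] = cE
    ab[4, n2 - 3] = 2.0 * cE

    # reaction cross-coupling at each node
    ab[1, 1::2] = p.k * M / (p.xi * fx**2)      # dF_M/dE
    u = (np.maximum(M, 0.0) / p.m)
    with np.errstate(over="ignore"):
        uh = u**p.h
        denom = (1.0 + uh) ** 2
        num = np.where(u > 0, u ** (p.h - 1.0), 0.0 if p.h > 1 else 1.0)
    ab[3, 0::2] = -p.nuE * p.h * num / (p.m * denom)  # dF_E/dM
    return ab


def _jac_sparse(p: ModelParams, grid: SpatialGrid, y: np.ndarray) -> sparse.csc_matrix:
    ab = _jac_banded(p, grid, y)
    return sparse.diags(
        [ab[0, 2:], ab[1, 1:], ab[2], ab[3, :-1], ab[4, :-2]],
        offsets=[2, 1, 0, -1, -2],
        format="csc",
    )


def _residuals(y: np.ndarray, f: np.ndarray, atol: float) -> tuple[float, float]:
    """Normalized steady-state residuals (per species)."""
    rM = np.max(np.abs(f[0::2])) / (np.max(np.abs(y[0::2])) + atol)
    rE = np.max(np.abs(f[1::2])) / (np.max(np.abs(y[1::2])) + atol)
    return rM, rE


def _default_t_max(p: ModelParams, y: np.ndarray) -> float:
    """Stopping-time guard: 50 / (slowest effective degradation rate)."""
    Emax = float(np.max(y[1::2])) if y.size else 0.0
    k_eff = p.k / (1.0 + Emax / p.xi)
    mu_eff = p.mu / (1.0 + Emax / p.zeta)
    return 50.0 / max(min(k_eff, mu_eff), 1e-300)


# ---------------------------------------------------------------------------
# Steady state
# ---------------------------------------------------------------------------

def solve_steady_state(
    p: ModelParams,
    opts: SolverOptions | None = None,
    init: ProfileSet | None = None,
) -> ProfileSet:
    """Relax the system to its steady state.

    Pseudo-transient continuation: backward-Euler steps whose time step
    doubles after every accepted step, each solved by Newton iteration on
    the banded linearization; non-convergent Newton shrinks the step.
    When the steady-state criterion is met a direct Newton polish of the
    algebraic system tightens the residual toward round-off.

    Never raises on failure: non-convergence or blow-up is reported via
    ``converged=False`` and ``message``.
    """
    opts = opts or SolverOptions()
    bad = validate_params(p)
    if bad:
        raise ValueError("invalid parameters: " + "; ".join(bad))
    grid = SpatialGrid(p.L, opts.Nx)
    n2 = 2 * grid.Nx

    if init is not None:
        y = np.empty(n2)
        if init.grid.Nx == grid.Nx and init.grid.L == grid.L:
            y[0::2], y[1::2] = init.M, init.E
        else:  # re-grid by interpolation in relative coordinates
            y[0::2] = np.interp(grid.r, init.grid.r, init.M)
            y[1::2] = np.interp(grid.r, init.grid.r, init.E)
    else:
        y = np.zeros(n2)
    y = np.maximum(y, 0.0)

    rate_scale = max(p.k, p.mu, 1e-12)
    dt = 1e-2 / rate_scale
    t = 0.0
    message = ""
    converged = False

    for _ in range(opts.max_steps):
        f = _rhs_vec(p, grid, y)
        rM, rE = _residuals(y, f, opts.atol)
        if max(rM, rE) < opts.ss_tol:
            converged = True
            break
        if np.max(y) > opts.overflow:
            message = "blow-up: concentration exceeded overflow guard"
            break
        # pseudo-time is only capped explicitly: residual contraction in
        # pseudo-transient continuation is per-step, so max_steps and the
        # overflow guard bound the work when t_max is unset
        if opts.t_max is not None and t > opts.t_max:
            message = f"no steady state before t_max={opts.t_max:.3g}"
            break

        # residual-safeguarded step: reject Newton solutions that inflate
        # the steady-state residual (guards against overshoot to spurious
        # large-concentration states when dt has grown aggressively)
        res_old = max(rM, rE)
        accepted = False
        for _try in range(16):
            y_new, ok = _backward_euler_step(p, grid, y, f, dt, opts)
            if ok:
                f_new = _rhs_vec(p, grid, np.maximum(y_new, 0.0))
                res_new = max(*_residuals(np.maximum(y_new, 0.0), f_new,
                                          opts.atol))
                if res_new <= 2.0 * res_old or res_new < opts.ss_tol:
                    accepted = True
                    break
            dt *= 0.25
        if not accepted:
            message = "step-size collapse in pseudo-transient continuation"
            break
        t += dt
        dt *= 2.0
        y = np.maximum(y_new, 0.0)
    else:
        message = f"no steady state within {opts.max_steps} steps"

    if converged and opts.newton_polish:
        y = _newton_polish(p, grid, y, opts)

    f = _rhs_vec(p, grid, y)
    rM, rE = _residuals(y, f, opts.atol)
    return ProfileSet(
        grid, y[0::2].copy(), y[1::2].copy(),
        converged=converged, t_elapsed=t, residual=max(rM, rE),
        message=message,
    )


def _backward_euler_step(
    p: ModelParams,
    grid: SpatialGrid,
    y0: np.ndarray,
    f0: np.ndarray,
    dt: float,
    opts: SolverOptions,
) -> tuple[np.ndarray, bool]:
    """One Newton-solved backward-Euler step; returns (y_new, success)."""
    y = np.maximum(y0 + dt * f0, 0.0)  # explicit predictor
    scale = np.max(np.abs(y0)) + opts.atol
    for _ in range(8):
        f = _rhs_vec(p, grid, y)
        if not np.all(np.isfinite(f)):
            return y0, False
        G = y - y0 - dt * f
        ab = -dt * _jac_banded(p, grid, y)
        ab[2] += 1.0
        try:
            delta = solve_banded((2, 2), ab, -G)
        except Exception:
            return y0, False
        y = y + delta
        if not np.all(np.isfinite(y)):
            return y0, False
        if np.max(np.abs(delta)) < 1e-10 * scale + 1e-13 * np.max(np.abs(y)):
            return y, True
    # accept if the implicit equation is nearly satisfied anyway
    f = _rhs_vec(p, grid, y)
    G = y - y0 - dt * f
    if np.max(np.abs(G)) < 1e-7 * scale:
        return y, True
    return y0, False


def _newton_polish(
    p: ModelParams, grid: SpatialGrid, y: np.ndarray, opts: SolverOptions
) -> np.ndarray:
    """Direct Newton on the steady-state equations; keeps the best iterate."""
    best = y
    f = _rhs_vec(p, grid, y)
    best_res = np.max(np.abs(f))
    for _ in range(6):
        ab = _jac_banded(p, grid, y)
        try:
            delta = solve_banded((2, 2), ab, -f)
        except Exception:
            break
        y = y + delta
        if not np.all(np.isfinite(y)) or np.min(y) < -1e-9 * (np.max(np.abs(y)) + 1):
            break
        y = np.maximum(y, 0.0)
        f = _rhs_vec(p, grid, y)
        res = np.max(np.abs(f))
        if res < best_res:
            best, best_res = y, res
        if res < 1e-14 * (np.max(np.abs(y)) + opts.atol):
            break
    return best


# ---------------------------------------------------------------------------
# Transients
# ---------------------------------------------------------------------------

def simulate_transient(
    p: ModelParams,
    opts: SolverOptions,
    init: ProfileSet,
    t_end: float,
    checkpoints: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the system from ``init`` up to ``t_end`` (adaptive BDF).

    Snapshots are returned at the integrator's accepted steps plus any
    requested checkpoint times; the final snapshot is at ``t_end``.
    """
    if not t_end > 0:
        raise ValueError("t_end must be positive")
    grid = init.grid
    y0 = np.empty(2 * grid.Nx)
    y0[0::2], y0[1::2] = init.M, init.E
    sol = solve_ivp(
        lambda t, y: _rhs_vec(p, grid, y),
        (0.0, t_end),
        y0,
        method="BDF",
        jac=lambda t, y: _jac_sparse(p, grid, y),
        rtol=opts.rtol,
        atol=opts.atol,
        dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"transient integration failed: {sol.message}")
    times = sol.t
    if checkpoints is not None:
        times = np.union1d(times, np.asarray(checkpoints, dtype=float))
        times = times[(times >= 0) & (times <= t_end)]
    Y = sol.sol(times).T
    return Trajectory(grid, times, Y[:, 0::2].copy(), Y[:, 1::2].copy())


def relax_after_perturbation(
    base: ProfileSet,
    p_perturbed: ModelParams,
    opts: SolverOptions | None = None,
) -> RelaxationResult:
    """Time the relaxation from ``base`` to the perturbed steady state.

    Integrates the system from the converged base profile under the
    perturbed parameters in geometrically growing chunks, scanning the
    steady-state criterion (at the transient tolerance) at every accepted
    integrator step.  ``t_max_total`` tracks the extremum of the spatially
    integrated morphogen: its maximum when production was increased, its
    minimum when decreased.
    """
    opts = opts or SolverOptions()
    if not base.converged:
        raise ValueError("base profile must be converged")
    grid = base.grid
    y = np.empty(2 * grid.Nx)
    y[0::2], y[1::2] = base.M, base.E
    w = grid.node_weights

    f = _rhs_vec(p_perturbed, grid, y)
    rM, rE = _residuals(y, f, opts.atol)
    if max(rM, rE) < opts.ss_tol_transient:
        final = ProfileSet(grid, y[0::2].copy(), y[1::2].copy(),
                           converged=True, residual=max(rM, rE))
        return RelaxationResult(0.0, 0.0, 0.0, final)

    # maximize total M if production was stepped up, minimize if stepped down
    sense = 1.0 if float(f[0::2] @ w) >= 0 else -1.0

    rate_scale = max(p_perturbed.k, p_perturbed.mu, 1e-12)
    chunk = (opts.check_interval if opts.check_interval is not None
             else 0.05 / rate_scale)
    t = 0.0
    t_ss = None
    mass_best = sense * float(y[0::2] @ w)
    t_best = 0.0
    t_cap = opts.t_max if opts.t_max is not None else None

    while t_ss is None:
        cap = t_cap if t_cap is not None else _default_t_max(p_perturbed, y)
        if t > cap:
            break
        sol = solve_ivp(
            lambda tt, yy: _rhs_vec(p_perturbed, grid, yy),
            (t, t + chunk),
            y,
            method="BDF",
            jac=lambda tt, yy: _jac_sparse(p_perturbed, grid, yy),
            rtol=opts.rtol,
            atol=opts.atol,
        )
        if not sol.success:
            break
        for j in range(1, len(sol.t)):
            yj = sol.y[:, j]
            mass = sense * float(yj[0::2] @ w)
            if mass > mass_best:
                mass_best, t_best = mass, float(sol.t[j])
            fj = _rhs_vec(p_perturbed, grid, yj)
            rM, rE = _residuals(yj, fj, opts.atol)
            if max(rM, rE) < opts.ss_tol_transient:
                t_ss = float(sol.t[j])
                y = yj
                break
        else:
            y = sol.y[:, -1]
            t = float(sol.t[-1])
            chunk *= 4.0
        if np.max(y) > opts.overflow:
            break

    converged = t_ss is not None
    if not converged:
        t_ss = t
    f = _rhs_vec(p_perturbed, grid, y)
    rM, rE = _residuals(y, f, opts.atol)
    final = ProfileSet(grid, y[0::2].copy(), y[1::2].copy(),
                       converged=converged, t_elapsed=t_ss,
                       residual=max(rM, rE))
    return RelaxationResult(
        tau_delta=t_ss, t_max_total=t_best, t_ss=t_ss,
        final=final, converged=converged,
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def mass_balance_residual(ps: ProfileSet, p: ModelParams) -> dict[str, float | None]:
    """Relative production-degradation imbalance per species at steady state.

    With zero-flux boundaries the spatial integrals of production and
    degradation must balance at steady state; the residual is their
    relative mismatch.  ``None`` marks a species with zero total
    production (undefined residual).  In boundary_flux mode j0 counts as
    morphogen production.
    """
    if not ps.converged:
        raise ValueError("mass balance is defined for converged profiles")
    grid = ps.grid
    w = grid.node_weights
    terms = reaction_terms(p, grid, ps.M, ps.E)
    out: dict[str, float | None] = {}
    prod_M = float(terms.prod_M @ w)
    if p.source_mode == "boundary_flux" and p.j0:
        prod_M += p.j0
    deg_M = float(terms.deg_M @ w)
    out["M"] = abs(prod_M - deg_M) / prod_M if prod_M > 0 else None
    prod_E = float(terms.prod_E @ w)
    deg_E = float(terms.deg_E @ w)
    out["E"] = abs(prod_E - deg_E) / prod_E if prod_E > 0 else None
    return out
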