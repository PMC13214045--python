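"""Core model definition for expansion-repression (ER) morphogen patterning.

The model couples a morphogen ``M`` and an expander ``E`` on a 1D tissue
``x in [0, L]``.  The morphogen is produced in a source region at the left
edge and degraded at a rate that the expander suppresses; the expander is
produced where the morphogen is low (repression) and suppresses its own
degradation.  In dimensional form::

    dM/dt = D_M M'' - k M / (1 + E/xi) + nu_M * theta(w_M - x)
    dE/dt = D_E E'' - mu E / (1 + E/zeta) + nu_E * m^h / (m^h + M^h)

with zero-flux boundaries.  ``k`` and ``mu`` are upper limits for the two
degradation rates; the Hill term with threshold ``m`` and coefficient ``h``
implements morphogen repression of expander production.  The morphogen
source width ``w_M`` either scales with tissue length (``w_M = beta * L``),
is fixed (``w0``), or is replaced by a constant input flux ``j0`` at x=0.

Concentrations are in arbitrary model units, lengths in micrometres and
times in model time units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "ModelParams",
    "SpatialGrid",
    "ProfileSet",
    "ReactionTerms",
    "validate_params",
    "reaction_terms",
    "source_fraction",
]

SOURCE_MODES = ("scaling_width", "fixed_width", "boundary_flux")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of one morphogen-expander system.

    Attributes
    ----------
    DM, DE
        Morphogen / expander diffusivities (µm²/time).
    k, mu
        Maximal morphogen / expander degradation rates (1/time).
    nuM, nuE
        Morphogen / (maximal) expander production rates (conc/time).
    xi
        Expander concentration at which morphogen degradation is halved.
    zeta
        Expander concentration at which expander degradation is halved.
    m
        Morphogen concentration at which expander production is halved.
    h
        Hill coefficient of the expander-production repression (>= 1).
    beta
        Source fraction: source width is ``beta * L`` in scaling mode.
    L
        Tissue length (µm).
    source_mode
        ``scaling_width`` (w_M = beta*L), ``fixed_width`` (w_M = w0) or
        ``boundary_flux`` (no source region; flux j0 enters at x = 0).
    w0
        Fixed source width (µm), used in ``fixed_width`` mode.
    j0
        Input flux (conc·µm/time), used in ``boundary_flux`` mode.
    """

    DM: float
    DE: float
    k: float
    mu: float
    nuM: float
    nuE: float
    xi: float
    zeta: float
    m: float
    h: float = 2.0
    beta: float = 0.1
    L: float = 50.0
    source_mode: str = "scaling_width"
    w0: float | None = None
    j0: float | None = None

    @property
    def w_M(self) -> float:
        """Morphogen source width for the configured source mode."""
        if self.source_mode == "scaling_width":
            return self.beta * self.L
        if self.source_mode == "fixed_width":
            return float(self.w0)
        return 0.0  # boundary_flux: no distributed source

    def with_length(self, L: float) -> "ModelParams":
        return replace(self, L=float(L))

    def with_production(self, nuM: float) -> "ModelParams":
        return replace(self, nuM=float(nuM))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)


def validate_params(p: ModelParams) -> list[str]:
    """Check all parameter invariants; return a list of violations.

    Never raises: an empty list means the parameter set is valid, every
    entry names the offending field and the rule it breaks.
    """
    bad: list[str] = []
    for name in ("DM", "DE", "k", "mu", "nuM", "nuE", "xi", "zeta", "m"):
        v = getattr(p, name)
        if not np.isfinite(v) or v < 0:
            bad.append(f"{name}: must be finite and nonnegative, got {v}")
        elif v == 0 and name in ("DM", "DE", "k", "mu", "xi", "zeta", "m"):
            bad.append(f"{name}: must be strictly positive, got 0")
    if not (p.h >= 1):
        bad.append(f"h: Hill coefficient must be >= 1, got {p.h}")
    if not (0 < p.beta < 1):
        bad.append(f"beta: source fraction must lie in (0, 1), got {p.beta}")
    if not (p.L > 0):
        bad.append(f"L: tissue length must be positive, got {p.L}")
    if p.source_mode not in SOURCE_MODES:
        bad.append(f"source_mode: must be one of {SOURCE_MODES}, got {p.source_mode!r}")
    elif p.source_mode == "fixed_width":
        if p.w0 is None or not (0 < p.w0 < p.L):
            bad.append(f"w0: fixed source width must satisfy 0 < w0 < L, got {p.w0}")
    elif p.source_mode == "boundary_flux":
        if p.j0 is None or not (p.j0 >= 0):
            bad.append(f"j0: input flux must be nonnegative, got {p.j0}")
    return bad


@dataclass
class SpatialGrid:
    """Uniform node grid on [0, L] with Nx nodes (inclusive endpoints)."""

    L: float
    Nx: int
    positions: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.Nx < 3:
            raise ValueError(f"Nx must be >= 3, got {self.Nx}")
        if not self.L > 0:
            raise ValueError(f"L must be positive, got {self.L}")
        self.positions = np.linspace(0.0, self.L, self.Nx)

    @property
    def dx(self) -> float:
        return self.L / (self.Nx - 1)

    @property
    def r(self) -> np.ndarray:
        """Relative coordinates r = x/L in [0, 1]."""
        return self.positions / self.L

    @property
    def node_weights(self) -> np.ndarray:
        """Control-volume widths (trapezoid weights): dx/2 at ends."""
        w = np.full(self.Nx, self.dx)
        w[0] = w[-1] = 0.5 * self.dx
        return w


@dataclass
class ProfileSet:
    """Steady-state (or snapshot) concentration profiles on a grid."""

    grid: SpatialGrid
    M: np.ndarray
    E: np.ndarray
    converged: bool = False
    t_elapsed: float = 0.0
    residual: float = np.inf
    message: str = ""

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.E = np.asarray(self.E, dtype=float)
        if self.M.shape != (self.grid.Nx,) or self.E.shape != (self.grid.Nx,):
            raise ValueError(
                f"profile arrays must have shape ({self.grid.Nx},); "
                f"got M{self.M.shape}, E{self.E.shape}"
            )


class ReactionTerms(NamedTuple):
    """Per-node production and degradation fields (concentration/time)."""

    prod_M: np.ndarray
    deg_M: np.ndarray
    prod_E: np.ndarray
    deg_E: np.ndarray


def source_fraction(p: ModelParams, grid: SpatialGrid) -> np.ndarray:
    """Fraction of each node's control volume inside the source region.

    The source indicator theta(w_M - x) is discretized by the fractional
    overlap of each control volume [x_i - dx/2, x_i + dx/2] (clipped to
    [0, L]) with [0, w_M), so total production varies continuously as w_M
    crosses grid nodes.  Returns zeros in boundary_flux mode.
    """
    wM = p.w_M
    if wM <= 0:
        return np.zeros(grid.Nx)
    x = grid.positions
    half = 0.5 * grid.dx
    left = np.clip(x - half, 0.0, grid.L)
    right = np.clip(x + half, 0.0, grid.L)
    width = right - left
    overlap = np.clip(np.minimum(right, wM) - left, 0.0, None)
    return overlap / width


def hill_repression(M: np.ndarray, m: float, h: float) -> np.ndarray:
    """Repressive Hill function m^h / (m^h + M^h), stable for large M."""
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + (np.maximum(M, 0.0) / m) ** h)


def reaction_terms(
    p: ModelParams, grid: SpatialGrid, M: np.ndarray, E: np.ndarray
) -> ReactionTerms:
    """Evaluate production and degradation fields for both species.

    Degradation is returned as a field (rate × concentration), so the
    effective per-molecule morphogen degradation rate is k/(1 + E/xi),
    bounded above by k, and analogously mu/(1 + E/zeta) for the expander.
    """
    M = np.asarray(M, dtype=float)
    E = np.asarray(E, dtype=float)
    if M.shape != (grid.Nx,) or E.shape != (grid.Nx,):
        raise ValueError(
            f"arrays must match grid with Nx={grid.Nx}; got M{M.shape}, E{E.shape}"
        )
    prod_M = p.nuM * source_fraction(p, grid)
    deg_M = p.k * M / (1.0 + E / p.xi)
    prod_E = p.nuE * hill_repression(M, p.m, p.h)
    deg_E = p.mu * E / (1.0 + E / p.zeta)
    return ReactionTerms(prod_M, deg_M, prod_E, deg_E)
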