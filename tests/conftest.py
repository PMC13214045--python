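import dataclasses

import numpy as np
import pytest

from morphoscale import (
    ModelParams,
    ProfileSet,
    SolverOptions,
    SpatialGrid,
    solve_steady_state,
)


def no_feedback(DM=1.0, k=1.0, nuM=1.0, L=10.0, beta=0.1):
    """Degenerate parameters reducing the model to the linear SDD system.

    Feedback thresholds pushed far above any reachable concentration and
    expander production switched off, so the morphogen obeys
    D M'' - k M + nu theta(wM - x) = 0 exactly.
    """
    return ModelParams(
        DM=DM, DE=1.0, k=k, mu=1.0, nuM=nuM, nuE=0.0,
        xi=1e12, zeta=1e12, m=1.0, h=2.0, beta=beta, L=L,
    )


# two converging feedback systems at L = 50 µm: one with a nearly uniform
# expander (high DE, slow turnover), one with a strongly position-dependent
# expander (fast turnover, low xi)
FIXTURE_SYSTEMS = {
    "uniform_expander": ModelParams(
        DM=20.0, DE=50.0, k=0.5, mu=0.02, nuM=1.0, nuE=0.2,
        xi=0.1, zeta=0.5, m=0.3, h=4.0, beta=0.1, L=50.0),
    "position_dependent_expander": ModelParams(
        DM=5.0, DE=2.0, k=2.0, mu=0.5, nuM=2.0, nuE=1.0,
        xi=0.05, zeta=0.5, m=0.5, h=2.0, beta=0.1, L=50.0),
}


@pytest.fixture(scope="session")
def fixture_systems():
    """Converged steady states of the two reference feedback systems."""
    opts = SolverOptions(Nx=501)
    out = {}
    for name, p in FIXTURE_SYSTEMS.items():
        ps = solve_steady_state(p, opts)
        assert ps.converged, f"fixture system {name} failed to converge"
        out[name] = (p, ps)
    return out


def exponential_profile(lam: float, L: float, Nx: int = 1001,
                        amplitude: float = 1.0,
                        expander: float = 1.0) -> ProfileSet:
    """Analytic pure-exponential morphogen with a uniform expander."""
    grid = SpatialGrid(L, Nx)
    M = amplitude * np.exp(-grid.positions / lam)
    E = np.full(Nx, expander)
    return ProfileSet(grid, M, E, converged=True, residual=0.0)


@pytest.fixture(scope="session")
def exp_pair():
    """Fixed-shape exponential (lambda = 10 µm) at L1 = 50 and L2 = 100 µm."""
    return exponential_profile(10.0, 50.0), exponential_profile(10.0, 100.0)


@pytest.fixture(scope="session")
def smoke_sweep():
    """Seeded reduced sweep shared by the emergent-property tests."""
    from morphoscale.sweep import SweepConfig, aggregate_records, run_sweep

    cfg = SweepConfig(n_systems=200, seed=1)
    records = run_sweep(cfg)
    agg = aggregate_records(records, cfg)
    return cfg, records, agg


def perturbed(p: ModelParams, **kw) -> ModelParams:
    return dataclasses.replace(p, **kw)
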