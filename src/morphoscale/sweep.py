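"""Parameter-space sweeps over the morphogen-expander model.

Each sampled parameter set defines one "system".  A system is solved to
steady state at two tissue lengths (L1 and L2 = 2 L1, to measure scaling)
and, at L1, with the morphogen production rate stepped up and down by a
fold factor (to measure robustness and relaxation timing).  Systems that
fail to converge, blow up, or produce gradients that are non-monotone,
uninformative, or lack expander feedback in the target tissue are
filtered out with machine-readable reason codes; the survivors are
aggregated into binned metric profiles and summary correlations.

Sampling is log-uniform and fully reproducible: the RNG for draw ``i`` is
seeded from ``(seed, i)``, so any single system can be recomputed in
isolation and results are independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .analytic_limits import ShapeFit, fit_gradient_shape
from .dynamics import (
    RelaxationResult,
    SolverOptions,
    relax_after_perturbation,
    solve_steady_state,
)
from .metrics import (
    ExpanderSummary,
    MetricProfile,
    MonotonicityError,
    PatterningClassification,
    classify_scaling,
    default_r_grid,
    expander_summaries,
    precision_profile,
    robustness_profile,
    scaling_profile,
    useful_patterning_region,
)
from .model_core import ModelParams, ProfileSet, validate_params

__all__ = [
    "SweepConfig",
    "SystemRecord",
    "SweepAggregate",
    "sample_parameter_sets",
    "evaluate_system",
    "run_sweep",
    "aggregate_records",
    "records_table",
]

#: Log-uniform sampling bounds (model units).  These span effective decay
#: lengths from far below to far above the reference tissue length
#: L1 = 50 µm; diffusivities in µm²/t, rates in 1/t, production rates in
#: conc/t, thresholds in conc.
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "DM": (0.1, 100.0),
    "DE": (0.1, 100.0),
    "k": (1e-3, 10.0),
    "mu": (1e-3, 10.0),
    "nuM": (1e-3, 10.0),
    "nuE": (1e-3, 10.0),
    "xi": (1e-3, 10.0),
    "zeta": (1e-3, 10.0),
    "m": (1e-3, 10.0),
}


@dataclass
class SweepConfig:
    """Protocol and thresholds for one sweep campaign.

    Defaults follow the measurement protocol: tissue lengths L1 = 50 µm
    and L2 = 100 µm, production perturbed to 1.5x and 1/1.5x, precision
    cell size d = 0.02 L1 = 1 µm, high-scaling threshold 0.98 (a <2%
    boundary shift) and useful-patterning threshold 0.95.
    """

    n_systems: int = 100
    seed: int = 0
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES))
    h_choices: tuple[float, ...] = (2.0, 4.0, 8.0)
    beta: float = 0.1
    L1: float = 50.0
    L2: float = 100.0
    perturb_factor: float = 1.5
    cell_size: float = 1.0  # d = 0.02 * L1
    high_scaling_threshold: float = 0.98
    useful_threshold: float = 0.95
    informative_ratio: float = 0.5  # filter f4: require M(L)/M(0) below this
    feedback_rmin: float = 0.1      # filter f5: E > xi for all r >= this
    r_points: int = 101
    solver: SolverOptions = field(default_factory=lambda: SolverOptions(Nx=501))
    do_relaxation: bool = True

    def __post_init__(self) -> None:
        if not self.L2 > self.L1 > 0:
            raise ValueError("need L2 > L1 > 0")
        if not self.perturb_factor > 1:
            raise ValueError("perturb_factor must exceed 1")
        if self.n_systems < 0:
            raise ValueError("n_systems must be nonnegative")
        for name, (lo, hi) in self.ranges.items():
            if not (0 < lo < hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


@dataclass
class SystemRecord:
    """Everything computed for one sampled system."""

    index: int
    params: ModelParams
    passed: bool = False
    reasons: list[str] = field(default_factory=list)
    base_L1: ProfileSet | None = None
    base_L2: ProfileSet | None = None
    plus_L1: ProfileSet | None = None
    minus_L1: ProfileSet | None = None
    summary_L1: ExpanderSummary | None = None
    summary_L2: ExpanderSummary | None = None
    S: MetricProfile | None = None
    R: MetricProfile | None = None
    P: MetricProfile | None = None
    shape: ShapeFit | None = None
    classification: PatterningClassification | None = None
    relax_plus: RelaxationResult | None = None
    relax_minus: RelaxationResult | None = None


def sample_parameter_sets(cfg: SweepConfig) -> list[ModelParams]:
    """Draw ``n_systems`` parameter sets, log-uniformly and independently.

    Deterministic given the seed; draw ``i`` uses a child RNG seeded from
    ``(seed, i)`` so individual systems can be regenerated in isolation.
    """
    out: list[ModelParams] = []
    names = sorted(cfg.ranges)
    for i in range(cfg.n_systems):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, i]))
        draw = {
            name: float(np.exp(rng.uniform(*np.log(cfg.ranges[name]))))
            for name in names
        }
        h = float(rng.choice(cfg.h_choices))
        p = ModelParams(h=h, beta=cfg.beta, L=cfg.L1, **draw)
        bad = validate_params(p)
        if bad:  # pragma: no cover - ranges guarantee validity
            raise RuntimeError(f"sampled invalid parameters: {bad}")
        out.append(p)
    return out


def _converged_or_reason(ps: ProfileSet, label: str) -> str | None:
    if ps.converged:
        return None
    if "blow-up" in ps.message:
        return f"f2:{label}"
    return f"f1:{label}"


def _monotone_on_target(ps: ProfileSet, r_min: float) -> bool:
    mask = ps.grid.r >= r_min
    M = ps.M[mask]
    scale = float(np.max(np.abs(ps.M))) + 1e-300
    return not np.any(np.diff(M) > 1e-9 * scale)


def evaluate_system(p: ModelParams, cfg: SweepConfig, index: int = 0) -> SystemRecord:
    """Solve, filter and measure one system; never raises.

    Filters (applied in order, first failure recorded and evaluation cut
    short where later solves cannot change the verdict):

    * f1 — all steady-state solves converged
    * f2 — no blow-up
    * f3 — morphogen monotonically non-increasing on the target tissue
    * f4 — informative gradient: M(L)/M(0) < informative_ratio at L1
    * f5 — expander feedback active: E > xi for r >= feedback_rmin at
      both lengths
    """
    rec = SystemRecord(index=index, params=p)
    opts = cfg.solver
    r_grid = default_r_grid(cfg.r_points)

    base1 = solve_steady_state(p.with_length(cfg.L1), opts)
    rec.base_L1 = base1
    reason = _converged_or_reason(base1, "base_L1")
    if reason:
        rec.reasons.append(reason)
        return rec
    if not _monotone_on_target(base1, p.beta):
        rec.reasons.append("f3:base_L1")
        return rec
    if base1.M[0] <= 0 or base1.M[-1] / base1.M[0] >= cfg.informative_ratio:
        rec.reasons.append("f4:base_L1")
        return rec
    if np.any(base1.E[base1.grid.r >= cfg.feedback_rmin] <= p.xi):
        rec.reasons.append("f5:base_L1")
        return rec

    base2 = solve_steady_state(p.with_length(cfg.L2), opts, init=base1)
    rec.base_L2 = base2
    reason = _converged_or_reason(base2, "base_L2")
    if reason:
        rec.reasons.append(reason)
        return rec
    if not _monotone_on_target(base2, p.beta):
        rec.reasons.append("f3:base_L2")
        return rec
    if np.any(base2.E[base2.grid.r >= cfg.feedback_rmin] <= p.xi):
        rec.reasons.append("f5:base_L2")
        return rec

    p1 = p.with_length(cfg.L1)
    plus = solve_steady_state(p1.with_production(p.nuM * cfg.perturb_factor),
                              opts, init=base1)
    minus = solve_steady_state(p1.with_production(p.nuM / cfg.perturb_factor),
                               opts, init=base1)
    rec.plus_L1, rec.minus_L1 = plus, minus
    for ps, label in ((plus, "plus_L1"), (minus, "minus_L1")):
        reason = _converged_or_reason(ps, label)
        if reason:
            rec.reasons.append(reason)
            return rec

    try:
        rec.S = scaling_profile(base1, base2, r_grid)
        rec.R = robustness_profile(base1, plus, minus, r_grid)
    except MonotonicityError as err:
        rec.reasons.append(f"f3:{err}")
        return rec
    rec.P = precision_profile(base1, cfg.cell_size, r_grid)
    rec.summary_L1 = expander_summaries(base1, p1)
    rec.summary_L2 = expander_summaries(base2, p.with_length(cfg.L2))
    try:
        rec.shape = fit_gradient_shape(base1, (p.beta + 0.05, 0.95))
    except ValueError:
        rec.shape = None
    cls = classify_scaling(rec.S, cfg.high_scaling_threshold,
                           target_region=(p.beta, 1.0))
    cls.useful_intervals = useful_patterning_region(
        rec.S, rec.R, rec.P, cfg.useful_threshold)
    rec.classification = cls
    rec.passed = True

    if cfg.do_relaxation:
        rec.relax_plus = relax_after_perturbation(
            base1, p1.with_production(p.nuM * cfg.perturb_factor), opts)
        rec.relax_minus = relax_after_perturbation(
            base1, p1.with_production(p.nuM / cfg.perturb_factor), opts)
    return rec


def run_sweep(cfg: SweepConfig, progress: bool = False) -> list[SystemRecord]:
    """Sample and evaluate a full campaign (order-independent records)."""
    params = sample_parameter_sets(cfg)
    records = []
    for i, p in enumerate(params):
        records.append(evaluate_system(p, cfg, index=i))
        if progress and (i + 1) % 50 == 0:
            npass = sum(r.passed for r in records)
            print(f"  evaluated {i + 1}/{cfg.n_systems} systems "
                  f"({npass} passing)", flush=True)
    return records


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class BinnedProfiles:
    """Mean and SD metric profiles over one (r*, f_E-bin) membership."""

    count: int
    mean_S: np.ndarray | None = None
    sd_S: np.ndarray | None = None
    mean_R: np.ndarray | None = None
    sd_R: np.ndarray | None = None
    mean_P: np.ndarray | None = None
    sd_P: np.ndarray | None = None


@dataclass
class SweepAggregate:
    """Figure-level aggregates of one sweep campaign."""

    r_values: np.ndarray
    n_total: int
    n_passing: int
    binned: dict[tuple[float, int], BinnedProfiles]
    useful_histogram: dict[int, np.ndarray]
    useful_counts: dict[int, int]
    lambda_pairs: list[tuple[float, float]]
    spearman_shape_fE: float | None
    spearman_tau_mu: float | None


def fE_bin(f_E: float, width: float = 0.1) -> int:
    """Index of the dynamic-range bin [i*width, (i+1)*width)."""
    return int(min(max(f_E, 0.0) / width, 1.0 / width - 1))


def aggregate_records(
    records: list[SystemRecord],
    cfg: SweepConfig,
    r_stars: tuple[float, ...] = (0.2, 0.5, 0.8),
) -> SweepAggregate:
    """Bin passing systems and compute the campaign-level summaries.

    * mean/SD scaling, robustness and precision profiles over systems
      with high scaling at each anchor position r*, split by f_E bin;
    * per-f_E-bin probability, at each position, that a (local or global)
      scaler patterns usefully there (S, R, P all above threshold);
    * relative expander half-decay lengths at the two tissue lengths for
      global scalers;
    * Spearman correlations of gradient-shape preference with f_E and of
      mean relaxation time with the integrated expander degradation rate.
    """
    passing = [r for r in records if r.passed]
    r_values = default_r_grid(cfg.r_points)
    thr = cfg.high_scaling_threshold

    binned: dict[tuple[float, int], BinnedProfiles] = {}
    for r_star in r_stars:
        members: dict[int, list[SystemRecord]] = {}
        for rec in passing:
            if rec.summary_L1 is None or rec.summary_L1.f_E is None:
                continue
            if rec.S.at(r_star) >= thr:
                members.setdefault(fE_bin(rec.summary_L1.f_E), []).append(rec)
        for b, recs in members.items():
            S = np.array([rc.S.values for rc in recs])
            R = np.array([rc.R.values for rc in recs])
            P = np.array([rc.P.values for rc in recs])
            binned[(r_star, b)] = BinnedProfiles(
                count=len(recs),
                mean_S=S.mean(axis=0), sd_S=S.std(axis=0),
                mean_R=R.mean(axis=0), sd_R=R.std(axis=0),
                mean_P=P.mean(axis=0), sd_P=P.std(axis=0),
            )

    useful_histogram: dict[int, np.ndarray] = {}
    useful_counts: dict[int, int] = {}
    for rec in passing:
        if (rec.classification is None or rec.classification.kind == "none"
                or rec.summary_L1 is None or rec.summary_L1.f_E is None):
            continue
        b = fE_bin(rec.summary_L1.f_E)
        ok = np.minimum(np.minimum(rec.S.values, rec.R.values),
                        rec.P.values) > cfg.useful_threshold
        useful_histogram[b] = useful_histogram.get(
            b, np.zeros(len(r_values))) + ok
        useful_counts[b] = useful_counts.get(b, 0) + 1
    for b in useful_histogram:
        useful_histogram[b] = useful_histogram[b] / useful_counts[b]

    lambda_pairs = []
    for rec in passing:
        if (rec.classification and rec.classification.kind == "global"
                and rec.summary_L1 and rec.summary_L2
                and rec.summary_L1.lambda_E is not None
                and rec.summary_L2.lambda_E is not None):
            lambda_pairs.append((rec.summary_L1.lambda_E / cfg.L1,
                                 rec.summary_L2.lambda_E / cfg.L2))

    shape_pairs = [(rec.shape.preference, rec.summary_L1.f_E)
                   for rec in passing
                   if rec.shape is not None and rec.summary_L1
                   and rec.summary_L1.f_E is not None]
    spearman_shape = None
    if len(shape_pairs) >= 3:
        spearman_shape = float(spearmanr(*zip(*shape_pairs)).statistic)

    tau_pairs = []
    for rec in passing:
        if (rec.relax_plus and rec.relax_minus and rec.summary_L1
                and rec.relax_plus.converged and rec.relax_minus.converged):
            tau = 0.5 * (rec.relax_plus.tau_delta + rec.relax_minus.tau_delta)
            tau_pairs.append((tau, rec.summary_L1.mu_bar))
    spearman_tau = None
    if len(tau_pairs) >= 3:
        spearman_tau = float(spearmanr(*zip(*tau_pairs)).statistic)

    return SweepAggregate(
        r_values=r_values,
        n_total=len(records),
        n_passing=len(passing),
        binned=binned,
        useful_histogram=useful_histogram,
        useful_counts=useful_counts,
        lambda_pairs=lambda_pairs,
        spearman_shape_fE=spearman_shape,
        spearman_tau_mu=spearman_tau,
    )


def records_table(records: list[SystemRecord]) -> pd.DataFrame:
    """One scalar-summary row per system (params, metrics, verdict)."""
    rows = []
    for rec in records:
        p = rec.params
        row: dict[str, object] = {
            "index": rec.index,
            "DM": p.DM, "DE": p.DE, "k": p.k, "mu": p.mu,
            "nuM": p.nuM, "nuE": p.nuE, "xi": p.xi, "zeta": p.zeta,
            "m": p.m, "h": p.h, "beta": p.beta,
            "passed": rec.passed,
            "reasons": ";".join(rec.reasons),
        }
        s = rec.summary_L1
        row["f_E"] = s.f_E if s else None
        row["lambda_E_over_L"] = (
            s.lambda_E / p.L if s and s.lambda_E is not None else None)
        row["w_E"] = s.w_E if s else None
        row["mu_bar"] = s.mu_bar if s else None
        row["shape_preference"] = rec.shape.preference if rec.shape else None
        row["classification"] = (
            rec.classification.kind if rec.classification else None)
        row["tau_plus"] = rec.relax_plus.tau_delta if rec.relax_plus else None
        row["tau_minus"] = rec.relax_minus.tau_delta if rec.relax_minus else None
        rows.append(row)
    return pd.DataFrame(rows)
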