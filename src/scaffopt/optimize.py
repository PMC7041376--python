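"""Strand-spacing optimization: maximize predicted mature-bone volume BO%.

For a chosen strand diameter ``D`` (set by the nozzle) and compressive load
``p``, the spacing ``d_fil`` is the one process parameter that can be varied
continuously on an FDM printer.  The design loop evaluates, for candidate
spacings, the chain

    geometry -> Biot poroelastic solve -> stimulus -> BO%

and minimizes the objective Omega(d_fil) = -BO% over the bounded interval
[D, 1100 um] (lower bound: strands in reciprocal contact; upper bound: the
largest spacing reported for comparable printed scaffolds).

The search is a coarse grid pre-scan followed by golden-section refinement
around the best grid point: derivative-free and robust to the plateau noise
a voxelized BO%(d_fil) response exhibits at coarse resolution.  Evaluations
are cached on (D, d_fil, p, resolution, layers), so re-visited spacings cost
nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd

from . import fem, geometry, mechanoreg

__all__ = [
    "OptimizerBounds",
    "OptimizationResult",
    "EvaluationConfig",
    "scaffold_objective",
    "objective",
    "optimize_d_fil",
    "optimize_scaffold",
    "factorial_campaign",
    "DEFAULT_D_LIST",
    "DEFAULT_P_LIST",
]

#: Strand diameters (um) and loads (MPa) of the factorial design campaign.
DEFAULT_D_LIST = (400.0, 500.0, 600.0, 700.0, 800.0)
DEFAULT_P_LIST = (0.2, 0.5, 1.0, 1.5)

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0  # 0.618...


@dataclass(frozen=True)
class OptimizerBounds:
    """Search interval for d_fil, um.  Lower bound is the strand diameter."""

    d_fil_min_um: float
    d_fil_max_um: float = 1100.0

    def __post_init__(self) -> None:
        if not 0 < self.d_fil_min_um <= self.d_fil_max_um:
            raise ValueError("need 0 < d_fil_min <= d_fil_max")

    @classmethod
    def for_diameter(cls, D_um: float, d_fil_max_um: float = 1100.0):
        return cls(d_fil_min_um=D_um, d_fil_max_um=d_fil_max_um)


@dataclass
class OptimizationResult:
    d_fil_opt_um: float
    BO_percent_max: float
    trace: list[tuple[float, float]]      # (d_fil, BO%) per evaluation
    n_evals: int
    converged: bool
    D_um: float | None = None
    p_MPa: float | None = None

    def __post_init__(self) -> None:
        if not self.trace:
            raise ValueError("trace must record at least one evaluation")


@dataclass
class EvaluationConfig:
    """Knobs of the geometry + FE evaluation behind one objective call.

    ``resolution_um`` is the voxel edge; ``n_layers`` the stacked strand
    layers of the periodic sub-volume.  Materials and load history follow
    the solver defaults unless overridden.
    """

    resolution_um: float = 100.0
    n_layers: int = 10
    overlap_fraction: float = 0.1
    mat_scaffold: fem.MaterialProperties = fem.SCAFFOLD_PLA
    mat_granulation: fem.MaterialProperties = fem.GRANULATION_TISSUE
    params: mechanoreg.MechanoregParams = field(
        default_factory=mechanoreg.MechanoregParams
    )
    ramp_time_s: float = 1.0
    eval_time_s: float = 1.0
    dt_s: float = 0.05
    _cache: dict = field(default_factory=dict, repr=False)


def scaffold_objective(
    D_um: float, p_MPa: float, config: EvaluationConfig | None = None
) -> Callable[[float], float]:
    """Return the cached objective Omega(d_fil) = -BO% for one (D, p)."""
    cfg = config if config is not None else EvaluationConfig()

    def omega(d_fil_um: float) -> float:
        key = (D_um, round(d_fil_um, 6), p_MPa, cfg.resolution_um, cfg.n_layers)
        if key in cfg._cache:
            return cfg._cache[key]
        spec = geometry.ScaffoldSpec(
            D_um=D_um, d_fil_um=d_fil_um, overlap_fraction=cfg.overlap_fraction
        )
        dom = geometry.DomainSpec(
            resolution_um=cfg.resolution_um, n_layers=cfg.n_layers
        )
        model = geometry.build_scaffold(spec, dom)
        system = fem.assemble_biot(model, cfg.mat_scaffold, cfg.mat_granulation)
        load = fem.LoadCase(
            p_MPa=p_MPa, ramp_time_s=cfg.ramp_time_s,
            eval_time_s=cfg.eval_time_s, dt_s=cfg.dt_s,
        )
        sol = fem.solve_compression(system, load)
        summary = mechanoreg.bone_fraction(
            sol.states, cfg.params, V_TOT_mm3=model.V_TOT_mm3
        )
        val = -summary.BO_percent
        cfg._cache[key] = val
        return val

    return omega


def objective(
    d_fil_um: float,
    D_um: float,
    p_MPa: float,
    config: EvaluationConfig | None = None,
) -> float:
    """One-shot evaluation of Omega(d_fil) = -BO% (uncached across calls
    unless a shared config is passed)."""
    return scaffold_objective(D_um, p_MPa, config)(d_fil_um)


def optimize_d_fil(
    omega: Callable[[float], float],
    bounds: OptimizerBounds,
    n_prescan: int = 8,
    tol_um: float = 10.0,
    budget: int = 50,
    x0_um: float | None = None,
    D_um: float | None = None,
    p_MPa: float | None = None,
) -> OptimizationResult:
    """Minimize Omega(d_fil) on [d_fil_min, d_fil_max].

    Grid pre-scan (``n_prescan`` equispaced points, bounds included) locates
    the basin; golden-section refinement shrinks the bracket to ``tol_um``.
    An optional tentative start ``x0_um`` is evaluated first but never
    replaces the scan.  Returns the best spacing, the corresponding BO% and
    the full evaluation trace; ``converged`` is False if the evaluation
    budget ran out before the bracket closed.
    """
    lo, hi = bounds.d_fil_min_um, bounds.d_fil_max_um
    trace: list[tuple[float, float]] = []
    evals: dict[float, float] = {}

    def f(x: float) -> float:
        x = min(max(x, lo), hi)
        xr = round(x, 6)
        if xr not in evals:
            if len(evals) >= budget:
                raise _BudgetExhausted
            val = omega(xr)
            evals[xr] = val
            trace.append((xr, -val))
        return evals[xr]

    class _BudgetExhausted(Exception):
        pass

    converged = False
    try:
        if x0_um is not None and lo <= x0_um <= hi:
            f(x0_um)
        if hi - lo <= tol_um:
            f(lo)
            f(hi)
            converged = True
        else:
            n = max(3, n_prescan)
            grid = [lo + (hi - lo) * i / (n - 1) for i in range(n)]
            for x in grid:
                f(x)
            best = min(evals, key=evals.get)
            i = min(range(n), key=lambda j: abs(grid[j] - best))
            a = grid[max(0, i - 1)]
            b = grid[min(n - 1, i + 1)]
            # golden-section on [a, b]
            x1 = b - _GOLDEN * (b - a)
            x2 = a + _GOLDEN * (b - a)
            f1, f2 = f(x1), f(x2)
            while b - a > tol_um:
                if f1 <= f2:
                    b, x2, f2 = x2, x1, f1
                    x1 = b - _GOLDEN * (b - a)
                    f1 = f(x1)
                else:
                    a, x1, f1 = x1, x2, f2
                    x2 = a + _GOLDEN * (b - a)
                    f2 = f(x2)
            converged = True
    except _BudgetExhausted:
        converged = False

    if not evals:
        raise RuntimeError("optimization made no successful evaluation")
    best = min(evals, key=evals.get)
    return OptimizationResult(
        d_fil_opt_um=best,
        BO_percent_max=-evals[best],
        trace=trace,
        n_evals=len(evals),
        converged=converged,
        D_um=D_um,
        p_MPa=p_MPa,
    )


def optimize_scaffold(
    D_um: float,
    p_MPa: float,
    config: EvaluationConfig | None = None,
    d_fil_max_um: float = 1100.0,
    **kw,
) -> OptimizationResult:
    """Optimize the strand spacing of a printed scaffold for one (D, p)."""
    bounds = OptimizerBounds.for_diameter(D_um, d_fil_max_um)
    omega = scaffold_objective(D_um, p_MPa, config)
    return optimize_d_fil(omega, bounds, D_um=D_um, p_MPa=p_MPa, **kw)


def factorial_campaign(
    D_list_um: Sequence[float],
    p_list_MPa: Sequence[float],
    objective_factory: Callable[[float, float], Callable[[float], float]] | None = None,
    config: EvaluationConfig | None = None,
    d_fil_max_um: float = 1100.0,
    **kw,
) -> pd.DataFrame:
    """Run the full D x p design campaign; one optimization per pair.

    ``objective_factory(D, p)`` may supply a surrogate objective (e.g. a mock
    in tests); by default the full FE chain is used.  Individual failures are
    recorded per row (``error`` column) and the campaign continues.
    """
    if not len(D_list_um) or not len(p_list_MPa):
        raise ValueError("D and p lists must be nonempty")
    rows = []
    for D in D_list_um:
        for p in p_list_MPa:
            row = {"D_um": D, "p_MPa": p}
            try:
                bounds = OptimizerBounds.for_diameter(D, d_fil_max_um)
                if objective_factory is not None:
                    omega = objective_factory(D, p)
                else:
                    omega = scaffold_objective(D, p, config)
                res = optimize_d_fil(omega, bounds, D_um=D, p_MPa=p, **kw)
                row.update(
                    d_fil_opt_um=res.d_fil_opt_um,
                    BO_percent_max=res.BO_percent_max,
                    n_evals=res.n_evals,
                    converged=res.converged,
                    error="",
                )
            except Exception as exc:  # campaign continues past per-cell failures
                row.update(
                    d_fil_opt_um=float("nan"), BO_percent_max=float("nan"),
                    n_evals=0, converged=False, error=str(exc),
                )
            rows.append(row)
    return pd.DataFrame(rows)
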