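"""Growth-maximizing multistart optimization of the four free parameters.

The objective is the daily growth rate returned by ``integrate_diel``.
Start points are drawn by Latin-hypercube sampling over the documented
bounds; each start is refined by a bounded Nelder-Mead simplex on
parameters rescaled to the unit box (the two maximal rates span orders of
magnitude, which stalls unscaled searches).  Given a seed the whole
procedure is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import qmc

from .params import (
    FREE_PARAMETER_BOUNDS,
    FixedParameters,
    FreeParameters,
    RunConfig,
    default_optimized_parameters,
)
from .simulator import integrate_diel

__all__ = ["OptimizationResult", "optimize", "reoptimize_vrp_segregated"]

_LOWER = np.array([lo for lo, _ in FREE_PARAMETER_BOUNDS.values()])
_UPPER = np.array([hi for _, hi in FREE_PARAMETER_BOUNDS.values()])


def _to_unit(x: np.ndarray) -> np.ndarray:
    return (x - _LOWER) / (_UPPER - _LOWER)


def _from_unit(u: np.ndarray) -> np.ndarray:
    return _LOWER + np.clip(u, 0.0, 1.0) * (_UPPER - _LOWER)


@dataclass
class OptimizationResult:
    best: FreeParameters
    best_growth: float
    starts: list[dict] = field(default_factory=list)  # per-start trajectories
    seed: int = 0
    n_starts: int = 0

    @property
    def boundary_solution(self) -> bool:
        """True if any component of the optimum sits on its bound."""
        x = self.best.as_array()
        return bool(np.any(np.isclose(x, _LOWER)) or np.any(np.isclose(x, _UPPER)))


def optimize(
    fixed: FixedParameters,
    config: RunConfig | None = None,
    n_starts: int | None = None,
    seed: int | None = None,
    include_defaults: bool = True,
    ftol: float = 1e-6,
    xtol: float = 1e-4,
    maxiter: int = 200,
) -> OptimizationResult:
    """Multistart maximization of the daily growth rate.

    ``include_defaults`` adds the variant's published optimum as one start,
    so the search never returns anything worse than refining that point.
    Returns every start's trajectory for multimodality diagnosis.
    """
    config = config or RunConfig()
    n_starts = n_starts if n_starts is not None else config.n_starts
    seed = seed if seed is not None else config.seed
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")

    def objective(u: np.ndarray) -> float:
        free = FreeParameters.from_array(_from_unit(u))
        try:
            return -integrate_diel(fixed, free, config).growth
        except RuntimeError:
            return np.inf  # integrator failure: reject the point

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    u_starts = [np.asarray(u) for u in sampler.random(n=n_starts)]
    if include_defaults:
        u_starts[0] = _to_unit(default_optimized_parameters(config.variant).as_array())

    starts: list[dict] = []
    best_u, best_g = None, -np.inf
    for u0 in u_starts:
        res = minimize(
            objective, u0, method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * 4,
            options={"fatol": ftol, "xatol": xtol, "maxiter": maxiter, "maxfev": 4 * maxiter},
        )
        g = -res.fun if np.isfinite(res.fun) else -np.inf
        starts.append({
            "start": FreeParameters.from_array(_from_unit(u0)),
            "converged": FreeParameters.from_array(_from_unit(res.x)),
            "growth": g,
            "success": bool(res.success),
            "nfev": int(res.nfev),
        })
        if g > best_g:
            best_g, best_u = g, res.x
    if best_u is None or not np.isfinite(best_g):
        raise RuntimeError("all optimization starts failed to produce a finite growth rate")
    return OptimizationResult(
        best=FreeParameters.from_array(_from_unit(best_u)),
        best_growth=best_g,
        starts=starts,
        seed=seed,
        n_starts=n_starts,
    )


def reoptimize_vrp_segregated(
    fixed: FixedParameters,
    config: RunConfig | None = None,
    n_grid: int = 9,
) -> tuple[FreeParameters, float]:
    """1-D re-optimization of the maximal RP rate for the segregated variant.

    The other three parameters stay at the unified optimum.  A coarse grid
    pre-scan brackets the maximum (and doubles as a unimodality check)
    before a bounded scalar refinement.
    """
    config = (config or RunConfig(variant="segregated")).replace(variant="segregated")
    base = default_optimized_parameters("unified")
    lo, hi = FREE_PARAMETER_BOUNDS["v_rp_max"]

    def growth_at(v: float) -> float:
        return integrate_diel(fixed, base.replace(v_rp_max=float(v)), config).growth

    grid = np.linspace(lo, hi, n_grid)
    gg = np.array([growth_at(v) for v in grid])
    k = int(np.argmax(gg))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(lambda v: -growth_at(v), bounds=(a, b), method="bounded",
                          options={"xatol": (hi - lo) * 1e-3})
    v_best, g_best = float(res.x), float(-res.fun)
    if gg[k] > g_best:  # grid point beat the refinement (flat objective)
        v_best, g_best = float(grid[k]), float(gg[k])
    return base.replace(v_rp_max=v_best), g_best
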