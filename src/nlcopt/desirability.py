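"""Derringer–Suich desirability functions and multi-response optimization.

Each response is mapped to a desirability d in [0, 1] according to its goal
(smaller-is-better, larger-is-better, or target-is-best); the overall
desirability is the weighted geometric mean D = (prod d_i^w_i)^(1/sum w_i),
so any fully undesirable response (d = 0) annihilates D.  The optimizer
maximizes D over the coded design region with a deterministic dense-grid
pass (bit-for-bit reproducible) followed by a local Nelder–Mead polish
started from the best grid cell; the polished point is only accepted when
it improves on the grid value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

from .surface import SurfaceModel

__all__ = [
    "d_minimize",
    "d_maximize",
    "d_target",
    "overall_desirability",
    "DesirabilityGoal",
    "DesirabilityResult",
    "optimize_desirability",
    "relative_prediction_error",
    "validation_record",
]


def _check_anchors(low: float, high: float) -> None:
    if not low < high:
        raise ValueError(f"low anchor must be below high anchor (got {low} >= {high})")


def d_minimize(y, low: float, high: float, s: float = 1.0):
    """Smaller-is-better transform: 1 at/below ``low``, 0 at/above ``high``."""
    _check_anchors(low, high)
    if s <= 0:
        raise ValueError("shape exponent s must be positive")
    y = np.asarray(y, dtype=float)
    d = np.clip((high - y) / (high - low), 0.0, 1.0) ** s
    return float(d) if d.ndim == 0 else d


def d_maximize(y, low: float, high: float, s: float = 1.0):
    """Larger-is-better transform: 0 at/below ``low``, 1 at/above ``high``."""
    _check_anchors(low, high)
    if s <= 0:
        raise ValueError("shape exponent s must be positive")
    y = np.asarray(y, dtype=float)
    d = np.clip((y - low) / (high - low), 0.0, 1.0) ** s
    return float(d) if d.ndim == 0 else d


def d_target(y, low: float, target: float, high: float,
             s_low: float = 1.0, s_high: float = 1.0):
    """Target-is-best transform rising to 1 at ``target`` and falling to 0 outside."""
    if not (low < target < high):
        raise ValueError(f"need low < target < high, got {low}, {target}, {high}")
    if s_low <= 0 or s_high <= 0:
        raise ValueError("shape exponents must be positive")
    y = np.asarray(y, dtype=float)
    up = np.clip((y - low) / (target - low), 0.0, 1.0) ** s_low
    down = np.clip((high - y) / (high - target), 0.0, 1.0) ** s_high
    d = np.where(y <= target, up, down)
    return float(d) if d.ndim == 0 else d


def overall_desirability(d: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Weighted geometric mean of individual desirabilities."""
    d = np.asarray(d, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("individual desirabilities must lie in [0, 1]")
    if weights is None:
        w = np.ones_like(d)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != d.shape:
            raise ValueError(f"weights shape {w.shape} != desirabilities shape {d.shape}")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    if np.any(d == 0):
        return 0.0
    return float(np.exp(np.sum(w * np.log(d)) / np.sum(w)))


@dataclass(frozen=True)
class DesirabilityGoal:
    """Goal specification for one response.

    ``transform="abs"`` applies the goal to |y| instead of y (useful for
    zeta potential when "small" means "close to zero" regardless of sign);
    anchors are then in |y| units.
    """

    goal: str  # "minimize" | "maximize" | "target"
    low: float
    high: float
    target: float | None = None
    s: float = 1.0
    weight: float = 1.0
    transform: str = "identity"  # "identity" | "abs"

    def __post_init__(self) -> None:
        if self.goal not in ("minimize", "maximize", "target"):
            raise ValueError(f"unknown goal {self.goal!r}")
        if self.transform not in ("identity", "abs"):
            raise ValueError(f"unknown transform {self.transform!r}")
        _check_anchors(self.low, self.high)
        if self.s <= 0 or self.weight <= 0:
            raise ValueError("shape exponent and weight must be positive")
        if self.goal == "target" and self.target is None:
            raise ValueError("target goal needs a target value")

    def __call__(self, y):
        y = np.abs(y) if self.transform == "abs" else y
        if self.goal == "minimize":
            return d_minimize(y, self.low, self.high, self.s)
        if self.goal == "maximize":
            return d_maximize(y, self.low, self.high, self.s)
        return d_target(y, self.low, self.target, self.high, self.s, self.s)


@dataclass
class DesirabilityResult:
    """Optimum found by :func:`optimize_desirability`."""

    settings_actual: dict[str, float]
    settings_coded: dict[str, float]
    predictions: dict[str, float]
    individual: dict[str, float]
    overall: float
    method: str
    n_evaluations: int
    on_boundary: bool
    degenerate: bool = False
    validation: "pd.DataFrame | None" = field(default=None, repr=False)


def _default_grid_points(k: int) -> int:
    # dense scan is cheap for the 2-factor case; back off for higher k
    return {1: 2001, 2: 401, 3: 101}.get(k, 21)


def optimize_desirability(models: Sequence[SurfaceModel],
                          goals: Mapping[str, DesirabilityGoal],
                          region: str = "box",
                          grid_points: int | None = None,
                          polish: bool = True) -> DesirabilityResult:
    """Maximize overall desirability over the coded design region.

    ``models`` supplies one fitted surface per response named in ``goals``;
    all models must share the same factors.  ``region`` is the coded box
    [-alpha, alpha]^k (default) or the coded ball of radius alpha.
    """
    if not models:
        raise ValueError("need at least one model")
    by_resp = {m.response: m for m in models}
    missing = set(goals) - set(by_resp)
    if missing:
        raise ValueError(f"no model for responses: {sorted(missing)}")
    use = [by_resp[r] for r in goals]
    factors = use[0].factors
    for m in use[1:]:
        if m.factors != factors:
            raise ValueError("all models must share the same factors")
    if region not in ("box", "ball"):
        raise ValueError(f"region must be 'box' or 'ball', got {region!r}")
    alpha = use[0].design_alpha
    if not np.isfinite(alpha):
        raise ValueError("models carry no design alpha; cannot bound the region")
    k = len(factors)
    gp = _default_grid_points(k) if grid_points is None else int(grid_points)

    axes = [np.linspace(-alpha, alpha, gp) for _ in range(k)]
    mesh = np.meshgrid(*axes, indexing="ij")
    coded_pts = np.column_stack([m.ravel() for m in mesh])
    if region == "ball":
        feasible = np.sum(coded_pts**2, axis=1) <= alpha**2 * (1 + 1e-12)
    else:
        feasible = np.ones(len(coded_pts), dtype=bool)

    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    actual_pts = centers + coded_pts * steps

    weights = np.array([goals[r].weight for r in goals])
    d_cols = []
    for resp, m in zip(goals, use):
        yhat = m.predict_grid(actual_pts)
        d_cols.append(np.asarray(goals[resp](yhat), dtype=float))
    d_mat = np.column_stack(d_cols)
    with np.errstate(divide="ignore"):
        logd = np.where(d_mat > 0, np.log(np.where(d_mat > 0, d_mat, 1.0)), -np.inf)
    D = np.exp((logd @ weights) / weights.sum())
    D = np.where(np.all(d_mat > 0, axis=1), D, 0.0)
    D = np.where(feasible, D, -1.0)

    n_eval = int(feasible.sum())
    best_idx = int(np.argmax(D))
    best_D = float(D[best_idx])
    best_coded = coded_pts[best_idx].copy()

    degenerate = False
    if best_D <= 0.0:
        # no point with every response acceptable: report the point with the
        # largest single desirability rather than an arbitrary grid corner
        degenerate = True
        score = np.where(feasible[:, None], d_mat, -1.0).max(axis=1)
        best_idx = int(np.argmax(score))
        best_coded = coded_pts[best_idx].copy()
        best_D = float(max(D[best_idx], 0.0))

    method = f"grid[{gp}^{k}]"

    def neg_D(c: np.ndarray) -> float:
        if region == "ball" and float(c @ c) > alpha**2 * (1 + 1e-12):
            return 1.0  # infeasible
        pt = centers + np.clip(c, -alpha, alpha) * steps
        ds = [float(goals[r](m.predict_grid(pt[None, :])[0])) for r, m in zip(goals, use)]
        return -overall_desirability(ds, weights)

    if polish and not degenerate:
        res = optimize.minimize(
            neg_D, best_coded, method="Nelder-Mead",
            bounds=[(-alpha, alpha)] * k,
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        n_eval += int(res.nfev)
        if -res.fun > best_D:
            best_D = float(-res.fun)
            best_coded = np.clip(res.x, -alpha, alpha)
            method += "+nelder-mead"

    best_actual = centers + best_coded * steps
    preds = {r: float(m.predict_grid(best_actual[None, :])[0])
             for r, m in zip(goals, use)}
    indiv = {r: float(goals[r](preds[r])) for r in goals}
    D_final = overall_desirability(list(indiv.values()), weights)
    on_boundary = bool(np.any(np.isclose(np.abs(best_coded), alpha, rtol=0, atol=1e-9))
                       or (region == "ball"
                           and np.isclose(best_coded @ best_coded, alpha**2, rtol=1e-9)))

    return DesirabilityResult(
        settings_actual={f.name: float(a) for f, a in zip(factors, best_actual)},
        settings_coded={f.name: float(c) for f, c in zip(factors, best_coded)},
        predictions=preds,
        individual=indiv,
        overall=float(D_final),
        method=method,
        n_evaluations=n_eval,
        on_boundary=on_boundary,
        degenerate=degenerate,
    )


def relative_prediction_error(measured: float, predicted: float) -> float:
    """|measured - predicted| / |measured| as a percentage."""
    if measured == 0:
        raise ZeroDivisionError("relative prediction error undefined for measured = 0")
    return abs(measured - predicted) / abs(measured) * 100.0


def validation_record(measured: Mapping[str, float],
                      predicted: Mapping[str, float]) -> "pd.DataFrame":
    """Measured vs predicted table with relative prediction errors (%)."""
    import pandas as pd

    common = [r for r in predicted if r in measured]
    rows = [(r, measured[r], predicted[r],
             relative_prediction_error(measured[r], predicted[r])) for r in common]
    return pd.DataFrame(
        rows, columns=["response", "measured", "predicted", "relative_error_pct"]
    ).set_index("response")
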