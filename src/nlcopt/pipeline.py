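"""End-to-end study pipeline: design table -> fitted models -> optimum.

:class:`StudyConfig` captures every choice the pipeline makes (model class
per response, desirability goals and anchors, optimizer region/grid) so a
run is fully reproducible from its JSON serialization.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np

from . import datasets
from .desirability import (DesirabilityGoal, DesirabilityResult,
                           optimize_desirability, validation_record)
from .doe import DesignMatrix, Factor
from .io import load_design_table
from .surface import ResponseSet, SelectionResult, SurfaceModel, select_model

__all__ = ["ModelSpec", "GoalSpec", "StudyConfig", "run_full_pipeline", "fit_study_models"]


@dataclass(frozen=True)
class ModelSpec:
    """Per-response model choice: an explicit class or ``"auto"`` selection.

    ``factors`` optionally restricts the polynomial to named factors (e.g.
    a zeta-potential model in the surfactant amount only).
    """

    model_class: str = "auto"
    factors: tuple[str, ...] | None = None


@dataclass(frozen=True)
class GoalSpec:
    """Per-response desirability goal; ``low``/``high`` anchors default to
    the observed response range in the design data."""

    goal: str = "minimize"
    low: float | None = None
    high: float | None = None
    target: float | None = None
    s: float = 1.0
    weight: float = 1.0
    transform: str = "identity"


@dataclass
class StudyConfig:
    """Complete configuration of a formulation-optimization study."""

    factors: tuple[Factor, ...] = field(default_factory=datasets.study_factors)
    design_csv: str | None = None  # None -> packaged study fixture
    models: dict[str, ModelSpec] = field(default_factory=dict)
    goals: dict[str, GoalSpec] = field(default_factory=dict)
    measured: dict[str, float] = field(default_factory=dict)
    alpha_level: float = 0.05
    region: str = "box"
    grid_points: int | None = None
    oil_density_g_per_ml: float = 0.92
    seed: int | None = None

    # -- serialization (round-trips exactly) -------------------------------

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["factors"] = [vars(f) for f in self.factors]
        d["models"] = {k: asdict(v) for k, v in self.models.items()}
        d["goals"] = {k: asdict(v) for k, v in self.goals.items()}
        text = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "StudyConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(
            factors=tuple(Factor(**f) for f in d.get("factors", [])),
            design_csv=d.get("design_csv"),
            models={k: ModelSpec(model_class=v.get("model_class", "auto"),
                                 factors=tuple(v["factors"]) if v.get("factors") else None)
                    for k, v in d.get("models", {}).items()},
            goals={k: GoalSpec(**v) for k, v in d.get("goals", {}).items()},
            measured=dict(d.get("measured", {})),
            alpha_level=float(d.get("alpha_level", 0.05)),
            region=d.get("region", "box"),
            grid_points=d.get("grid_points"),
            oil_density_g_per_ml=float(d.get("oil_density_g_per_ml", 0.92)),
            seed=d.get("seed"),
        )


def study_config() -> StudyConfig:
    """Configuration reproducing the packaged study's published analysis:
    pure-quadratic particle size, full second-order PdI, and a linear
    zeta-potential model in the surfactant amount, all goals
    smaller-is-better with observed-range anchors."""
    return StudyConfig(
        models={
            "particle_size": ModelSpec("PQ"),
            "pdi": ModelSpec("SO"),
            "zeta_potential": ModelSpec("FO", factors=("surfactant",)),
        },
        goals={r: GoalSpec("minimize") for r in datasets.RESPONSES},
        measured=dict(datasets.MEASURED_OPTIMUM),
    )


def fit_study_models(config: StudyConfig, design: DesignMatrix,
                     responses: ResponseSet) -> dict[str, SelectionResult]:
    """Fit (or select) one surface model per configured response."""
    out: dict[str, SelectionResult] = {}
    names = list(config.models) or list(responses.responses)
    for resp in names:
        mspec = config.models.get(resp, ModelSpec())
        fidx = None
        if mspec.factors is not None:
            fidx = [design.factor_names.index(n) for n in mspec.factors]
        if mspec.model_class == "auto":
            out[resp] = select_model(design, responses, resp,
                                     alpha_level=config.alpha_level, factor_idx=fidx)
        else:
            out[resp] = select_model(design, responses, resp,
                                     alpha_level=config.alpha_level,
                                     override=mspec.model_class, factor_idx=fidx)
    return out


def _resolve_goals(config: StudyConfig, responses: ResponseSet
                   ) -> dict[str, DesirabilityGoal]:
    goals: dict[str, DesirabilityGoal] = {}
    for resp, g in config.goals.items():
        low, high = g.low, g.high
        if low is None or high is None:
            lo_obs, hi_obs = responses.observed_range(resp)
            if g.transform == "abs":
                lo_obs, hi_obs = sorted((abs(lo_obs), abs(hi_obs)))
            low = lo_obs if low is None else low
            high = hi_obs if high is None else high
        goals[resp] = DesirabilityGoal(goal=g.goal, low=low, high=high,
                                       target=g.target, s=g.s, weight=g.weight,
                                       transform=g.transform)
    return goals


def run_full_pipeline(config: StudyConfig) -> dict:
    """Load data, fit models, optimize desirability, validate; return a
    JSON-serializable report."""
    if config.design_csv is None:
        design, responses = datasets.ccd_study()
    else:
        design, responses = load_design_table(config.design_csv, config.factors)

    selections = fit_study_models(config, design, responses)
    models = [s.model for s in selections.values()]
    goals = _resolve_goals(config, responses)
    optimum: DesirabilityResult = optimize_desirability(
        models, goals, region=config.region, grid_points=config.grid_points)

    report: dict = {
        "design": {
            "n_runs": design.n_runs,
            "alpha": design.alpha,
            "point_types": design.point_type_counts(),
            "factors": [vars(f) for f in design.factors],
        },
        "models": {
            resp: {
                "selected_class": sel.model.model_class,
                "selection_flag": sel.flag,
                "significant_candidates": list(sel.significant),
                **sel.model.to_dict(),
            }
            for resp, sel in selections.items()
        },
        "optimum": {
            "settings_actual": optimum.settings_actual,
            "settings_coded": optimum.settings_coded,
            "predictions": optimum.predictions,
            "individual_desirability": optimum.individual,
            "overall_desirability": optimum.overall,
            "method": optimum.method,
            "on_boundary": optimum.on_boundary,
            "degenerate": optimum.degenerate,
        },
    }
    if config.measured:
        vr = validation_record(config.measured, optimum.predictions)
        report["validation"] = {
            resp: {
                "measured": float(row["measured"]),
                "predicted": float(row["predicted"]),
                "relative_error_pct": float(row["relative_error_pct"]),
            }
            for resp, row in vr.iterrows()
        }
    return report


def format_report(report: Mapping) -> str:
    """Human-readable summary of a pipeline report."""
    lines = []
    d = report["design"]
    lines.append(f"Design: {d['n_runs']} runs "
                 f"({d['point_types']['factorial']} factorial, "
                 f"{d['point_types']['axial']} axial, "
                 f"{d['point_types']['center']} center), alpha={d['alpha']:.4f}")
    for resp, m in report["models"].items():
        lines.append(
            f"  {resp}: {m['selected_class']} model, R2={m['r_squared']:.4f}, "
            f"adjR2={m['adj_r_squared']:.4f}, p(model)={m['anova']['p_model']:.3g} "
            f"[{m['selection_flag']}]")
    opt = report["optimum"]
    settings = ", ".join(f"{k}={v:.1f}" for k, v in opt["settings_actual"].items())
    lines.append(f"Optimum (D={opt['overall_desirability']:.3f}): {settings}")
    for resp, yhat in opt["predictions"].items():
        lines.append(f"  predicted {resp} = {yhat:.4g} "
                     f"(d={opt['individual_desirability'][resp]:.3f})")
    if "validation" in report:
        for resp, v in report["validation"].items():
            lines.append(f"  measured {resp} = {v['measured']:.4g} "
                         f"(relative error {v['relative_error_pct']:.1f}%)")
    return "\n".join(lines)
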