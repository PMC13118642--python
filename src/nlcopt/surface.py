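"""Polynomial response-surface models for CCD data.

Fits ordinary-least-squares polynomial surfaces to per-run response means,
in four nested model classes:

* ``FO``  — first order (intercept + linear terms);
* ``TWI`` — first order plus two-way interactions;
* ``PQ``  — "pure quadratic": first order plus squared terms, no interactions;
* ``SO``  — full second order (linear + interactions + squares).

Each fit carries coefficients in both coded and actual units (the two are
alternative parameterizations of the same least-squares projection, so
their predictions agree to numerical precision), the coefficient of
determination, and an ANOVA record that splits the residual sum of squares
into lack-of-fit and pure error using the replicated center runs.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .doe import DesignMatrix, Factor

__all__ = [
    "MODEL_CLASSES",
    "ResponseSet",
    "AnovaRecord",
    "SurfaceModel",
    "SelectionResult",
    "model_terms",
    "term_name",
    "expand_terms",
    "fit_surface",
    "select_model",
    "predict",
    "SingularDesignError",
]

MODEL_CLASSES = ("FO", "TWI", "PQ", "SO")

# A term is a tuple of factor indices whose levels are multiplied together:
# () intercept, (i,) linear, (i, j) interaction, (i, i) quadratic.
Term = tuple[int, ...]


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the model matrix is rank deficient for the requested terms."""


@dataclass
class ResponseSet:
    """Per-run replicate summaries for one or more responses.

    ``table`` is long-format with columns ``run_id``, ``response``,
    ``mean``, ``sd``, ``n`` — the layout in which formulation studies
    report "mean ± SD of three analytical replicates".
    """

    table: pd.DataFrame

    REQUIRED = ("run_id", "response", "mean", "sd", "n")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"response table missing columns: {sorted(missing)}")
        t = self.table
        if (t["sd"] < 0).any():
            raise ValueError("replicate SD must be nonnegative")
        if (t["n"] < 1).any():
            raise ValueError("replicate count must be >= 1")
        if t.duplicated(["run_id", "response"]).any():
            raise ValueError("duplicate (run_id, response) rows")

    @property
    def responses(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.table["response"]))

    def means(self, response: str, run_ids: Sequence) -> np.ndarray:
        """Replicate means for ``response`` aligned to ``run_ids`` order."""
        sub = self.table[self.table["response"] == response]
        if sub.empty:
            raise KeyError(f"no rows for response {response!r}")
        by_run = sub.set_index("run_id")["mean"]
        missing = [r for r in run_ids if r not in by_run.index]
        if missing:
            raise KeyError(f"response {response!r} missing run_ids {missing}")
        return by_run.loc[list(run_ids)].to_numpy(dtype=float)

    def observed_range(self, response: str) -> tuple[float, float]:
        sub = self.table.loc[self.table["response"] == response, "mean"]
        if sub.empty:
            raise KeyError(f"no rows for response {response!r}")
        return float(sub.min()), float(sub.max())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ResponseSet":
        return cls(pd.read_csv(path))


def model_terms(k: int, model_class: str, factor_idx: Sequence[int] | None = None
                ) -> tuple[Term, ...]:
    """Canonical term list for ``model_class`` over ``k`` factors.

    Order: intercept, linear terms by factor order, two-way interactions in
    lexicographic order, quadratic terms by factor order.  ``factor_idx``
    restricts the model to a subset of factors (e.g. a straight line in the
    surfactant amount only).
    """
    if model_class not in MODEL_CLASSES:
        raise ValueError(f"unknown model class {model_class!r}; expected one of {MODEL_CLASSES}")
    idx = tuple(range(k)) if factor_idx is None else tuple(factor_idx)
    if any(i < 0 or i >= k for i in idx):
        raise ValueError(f"factor indices {idx} out of range for k={k}")
    terms: list[Term] = [()]
    terms += [(i,) for i in idx]
    if model_class in ("TWI", "SO"):
        terms += [(i, j) for i, j in itertools.combinations(idx, 2)]
    if model_class in ("PQ", "SO"):
        terms += [(i, i) for i in idx]
    return tuple(terms)


def term_name(term: Term, factor_names: Sequence[str]) -> str:
    if not term:
        return "intercept"
    if len(term) == 2 and term[0] == term[1]:
        return f"{factor_names[term[0]]}^2"
    return ":".join(factor_names[i] for i in term)


def _expand(levels: np.ndarray, terms: Sequence[Term]) -> np.ndarray:
    levels = np.atleast_2d(np.asarray(levels, dtype=float))
    cols = [np.ones(len(levels)) if not t
            else np.prod(levels[:, list(t)], axis=1) for t in terms]
    return np.column_stack(cols)


def expand_terms(design: DesignMatrix, model_class: str, units: str = "coded",
                 factor_idx: Sequence[int] | None = None) -> pd.DataFrame:
    """Model matrix (runs x terms) for ``design`` in the given unit system."""
    if units not in ("coded", "actual"):
        raise ValueError(f"units must be 'coded' or 'actual', got {units!r}")
    terms = model_terms(design.k, model_class, factor_idx)
    levels = design.coded() if units == "coded" else design.actual()
    X = _expand(levels, terms)
    names = [term_name(t, design.factor_names) for t in terms]
    return pd.DataFrame(X, columns=names, index=design.runs["run_id"])


@dataclass
class AnovaRecord:
    """ANOVA decomposition for one surface fit.

    ``sources`` maps ``model`` / ``residual`` / ``lack_of_fit`` /
    ``pure_error`` / ``total`` to (df, sum of squares, mean square); the
    F statistics test the overall model against the residual mean square
    and lack of fit against pure error.  Pure error comes from runs with
    identical factor settings (the replicated center points), so the
    lack-of-fit test is only available when the design has such replicates.
    """

    sources: dict[str, tuple[int, float, float]]
    f_model: float
    p_model: float
    f_lack_of_fit: float
    p_lack_of_fit: float

    def df(self, source: str) -> int:
        return self.sources[source][0]

    def ss(self, source: str) -> float:
        return self.sources[source][1]

    def ms(self, source: str) -> float:
        return self.sources[source][2]

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, *v) for k, v in self.sources.items()]
        return pd.DataFrame(rows, columns=["source", "df", "ss", "ms"]).set_index("source")


@dataclass
class SurfaceModel:
    """A fitted polynomial response surface for one response."""

    response: str
    model_class: str
    factors: tuple[Factor, ...]
    terms: tuple[Term, ...]
    coef_actual: np.ndarray
    coef_coded: np.ndarray
    r_squared: float
    adj_r_squared: float
    anova: AnovaRecord
    design_alpha: float = float("nan")
    term_pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(term_name(t, self.factor_names) for t in self.terms)

    def coded_radius(self, settings: Sequence[float]) -> float:
        c = [f.code(x) for f, x in zip(self.factors, settings)]
        return float(np.sqrt(np.sum(np.square(c))))

    def predict(self, settings: Sequence[float], units: str = "actual") -> float:
        """Evaluate the surface at one point given in ``units``.

        Extrapolation beyond the design's axial radius is allowed but
        triggers a warning.
        """
        settings = np.asarray(settings, dtype=float)
        if settings.shape != (len(self.factors),):
            raise ValueError(
                f"expected {len(self.factors)} factor settings, got shape {settings.shape}")
        if units == "actual":
            actual = settings
        elif units == "coded":
            actual = np.array([f.decode(c) for f, c in zip(self.factors, settings)])
        else:
            raise ValueError(f"units must be 'actual' or 'coded', got {units!r}")
        if np.isfinite(self.design_alpha):
            r = self.coded_radius(actual)
            if r > self.design_alpha * (1 + 1e-12):
                warnings.warn(
                    f"prediction at coded radius {r:.3f} extrapolates beyond the "
                    f"design region (alpha={self.design_alpha:.3f})",
                    stacklevel=2)
        return float((_expand(actual, self.terms) @ self.coef_actual)[0])

    def predict_grid(self, actual_points: np.ndarray) -> np.ndarray:
        """Vectorized evaluation at an (n, k) array of actual-unit points."""
        return _expand(actual_points, self.terms) @ self.coef_actual

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "model_class": self.model_class,
            "factors": [vars(f) for f in self.factors],
            "terms": [list(t) for t in self.terms],
            "term_names": list(self.term_names),
            "coef_actual": self.coef_actual.tolist(),
            "coef_coded": self.coef_coded.tolist(),
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
            "design_alpha": self.design_alpha,
            "term_pvalues": self.term_pvalues,
            "anova": {
                "sources": {k: list(v) for k, v in self.anova.sources.items()},
                "f_model": self.anova.f_model,
                "p_model": self.anova.p_model,
                "f_lack_of_fit": self.anova.f_lack_of_fit,
                "p_lack_of_fit": self.anova.p_lack_of_fit,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurfaceModel":
        an = d["anova"]
        return cls(
            response=d["response"],
            model_class=d["model_class"],
            factors=tuple(Factor(**f) for f in d["factors"]),
            terms=tuple(tuple(t) for t in d["terms"]),
            coef_actual=np.asarray(d["coef_actual"], dtype=float),
            coef_coded=np.asarray(d["coef_coded"], dtype=float),
            r_squared=float(d["r_squared"]),
            adj_r_squared=float(d["adj_r_squared"]),
            anova=AnovaRecord(
                sources={k: (int(v[0]), float(v[1]), float(v[2]))
                         for k, v in an["sources"].items()},
                f_model=float(an["f_model"]),
                p_model=float(an["p_model"]),
                f_lack_of_fit=float(an["f_lack_of_fit"]),
                p_lack_of_fit=float(an["p_lack_of_fit"]),
            ),
            design_alpha=float(d.get("design_alpha", float("nan"))),
            term_pvalues=dict(d.get("term_pvalues", {})),
        )


def save_models(models: Sequence[SurfaceModel], path) -> None:
    with open(path, "w") as fh:
        json.dump([m.to_dict() for m in models], fh, indent=2)


def load_models(path) -> list[SurfaceModel]:
    with open(path) as fh:
        return [SurfaceModel.from_dict(d) for d in json.load(fh)]


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Least squares via QR-based lstsq; rejects rank-deficient matrices."""
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify collinear columns by QR pivoting on the correlation scale
        norms = np.linalg.norm(X, axis=0)
        Q, R = np.linalg.qr(X / np.where(norms > 0, norms, 1.0))
        small = np.abs(np.diag(R)) < 1e-10
        bad = [names[i] for i in np.nonzero(small)[0]] or list(names)
        raise SingularDesignError(
            f"model matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear terms: {bad}")
    return beta


def fit_surface(design: DesignMatrix, responses: ResponseSet, response: str,
                model_class: str, factor_idx: Sequence[int] | None = None
                ) -> SurfaceModel:
    """OLS fit of ``model_class`` for one response on the per-run means.

    The fit is performed on the run means (the convention for CCD data
    reported as mean ± SD of analytical replicates); pure error in the
    ANOVA comes from runs with identical settings, i.e. the replicated
    center points, not from the analytical replicates.

    ``factor_idx`` restricts the polynomial to a subset of factors, e.g.
    ``factor_idx=[1]`` fits a straight line in the second factor only.
    """
    terms = model_terms(design.k, model_class, factor_idx)
    names = [term_name(t, design.factor_names) for t in terms]
    y = responses.means(response, design.runs["run_id"])
    n, p = len(y), len(terms)
    if n < p:
        raise ValueError(f"{n} runs cannot identify {p} terms ({model_class})")

    X_cod = _expand(design.coded(), terms)
    X_act = _expand(design.actual(), terms)
    beta_cod = _ols(X_cod, y, names)
    beta_act = _ols(X_act, y, names)

    fitted = X_cod @ beta_cod
    resid = y - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_mod = ss_tot - ss_res
    df_mod, df_res = p - 1, n - p
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_res if df_res > 0 else float("nan")

    # pure error from exact replicate settings (coded rounded to 9 dp)
    keys = [tuple(np.round(row, 9)) for row in design.coded()]
    groups: dict[tuple, list[int]] = {}
    for i, key in enumerate(keys):
        groups.setdefault(key, []).append(i)
    ss_pe = 0.0
    for idxs in groups.values():
        if len(idxs) > 1:
            vals = y[idxs]
            ss_pe += float(np.sum((vals - vals.mean()) ** 2))
    m = len(groups)
    df_pe = n - m
    df_lof = m - p
    ss_lof = ss_res - ss_pe

    ms_mod = ss_mod / df_mod if df_mod > 0 else float("nan")
    ms_res = ss_res / df_res if df_res > 0 else float("nan")
    if df_res > 0 and ms_res > 0:
        f_mod = ms_mod / ms_res
        p_mod = float(stats.f.sf(f_mod, df_mod, df_res))
    else:
        f_mod, p_mod = float("inf"), 0.0
    if df_pe > 0 and df_lof > 0 and ss_pe > 0:
        ms_lof, ms_pe = ss_lof / df_lof, ss_pe / df_pe
        f_lof = ms_lof / ms_pe
        p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
    else:
        ms_lof = ss_lof / df_lof if df_lof > 0 else float("nan")
        ms_pe = ss_pe / df_pe if df_pe > 0 else float("nan")
        f_lof, p_lof = float("nan"), float("nan")

    anova = AnovaRecord(
        sources={
            "model": (df_mod, ss_mod, ms_mod),
            "residual": (df_res, ss_res, ms_res),
            "lack_of_fit": (df_lof, ss_lof, ms_lof),
            "pure_error": (df_pe, ss_pe, ms_pe),
            "total": (n - 1, ss_tot, ss_tot / (n - 1) if n > 1 else float("nan")),
        },
        f_model=float(f_mod), p_model=p_mod,
        f_lack_of_fit=float(f_lof), p_lack_of_fit=p_lof,
    )

    # partial (type III) per-term p-values from the coded fit
    term_p: dict[str, float] = {}
    if df_res > 0 and ms_res > 0:
        XtX_inv = np.linalg.inv(X_cod.T @ X_cod)
        se = np.sqrt(np.diag(XtX_inv) * ms_res)
        tvals = beta_cod / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df_res)
        term_p = {nm: float(pv) for nm, pv in zip(names, pvals)}

    return SurfaceModel(
        response=response, model_class=model_class, factors=design.factors,
        terms=terms, coef_actual=beta_act, coef_coded=beta_cod,
        r_squared=r2, adj_r_squared=adj_r2, anova=anova,
        design_alpha=design.alpha, term_pvalues=term_p,
    )


def sequential_term_ss(design: DesignMatrix, responses: ResponseSet, response: str,
                       model_class: str, factor_idx: Sequence[int] | None = None
                       ) -> pd.DataFrame:
    """Type-I (sequential) sum of squares, adding terms in canonical order."""
    terms = model_terms(design.k, model_class, factor_idx)
    names = [term_name(t, design.factor_names) for t in terms]
    y = responses.means(response, design.runs["run_id"])
    X = _expand(design.coded(), terms)
    rows = []
    prev_ss = float(np.sum((y - y.mean()) ** 2))
    for j in range(1, len(terms) + 1):
        beta, *_ = np.linalg.lstsq(X[:, :j], y, rcond=None)
        ss_res = float(np.sum((y - X[:, :j] @ beta) ** 2))
        rows.append((names[j - 1], prev_ss - ss_res))
        prev_ss = ss_res
    return pd.DataFrame(rows, columns=["term", "seq_ss"]).set_index("term")


@dataclass
class SelectionResult:
    """Outcome of model-class selection for one response."""

    model: SurfaceModel
    candidates: tuple[str, ...]
    significant: tuple[str, ...]
    flag: str  # "ok" | "no significant model" | "override"

    @property
    def model_class(self) -> str:
        return self.model.model_class


def select_model(design: DesignMatrix, responses: ResponseSet, response: str,
                 candidates: Sequence[str] = MODEL_CLASSES,
                 alpha_level: float = 0.05,
                 override: str | None = None,
                 factor_idx: Sequence[int] | None = None) -> SelectionResult:
    """Choose a model class for one response.

    Default rule: among candidates whose overall F-test is significant
    (p < alpha_level) and whose lack-of-fit test does not reject
    (p >= alpha_level, or no test available), pick the highest adjusted R²,
    breaking ties toward fewer terms.  If none qualifies, the best
    adjusted-R² candidate is returned flagged ``"no significant model"``.
    An ``override`` class skips the rule (used to reproduce a published
    choice exactly).
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if override is not None:
        if override not in MODEL_CLASSES:
            raise ValueError(f"unknown override class {override!r}")
        m = fit_surface(design, responses, response, override, factor_idx)
        return SelectionResult(m, tuple(candidates), (), "override")

    fits = {c: fit_surface(design, responses, response, c, factor_idx)
            for c in candidates}
    ok = []
    for c, m in fits.items():
        sig = m.anova.p_model < alpha_level
        plof = m.anova.p_lack_of_fit
        lof_ok = (not np.isfinite(plof)) or plof >= alpha_level
        if sig and lof_ok:
            ok.append(c)
    pool = ok if ok else list(candidates)
    # highest adjusted R²; ties (within 1e-12) toward fewer terms
    best = min(pool, key=lambda c: (-round(fits[c].adj_r_squared, 12), len(fits[c].terms)))
    flag = "ok" if ok else "no significant model"
    return SelectionResult(fits[best], tuple(candidates), tuple(ok), flag)


def predict(model: SurfaceModel, settings: Sequence[float], units: str = "actual") -> float:
    """Evaluate ``model`` at one point (see :meth:`SurfaceModel.predict`)."""
    return model.predict(settings, units=units)
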