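"""Synthetic data generators mirroring the structure of a CCD formulation study.

Three generators cover the pipeline end to end without any external data:

* quadratic response surfaces with Gaussian replicate noise on a CCD
  (triplicate analytical measurements per run);
* biphasic burst-plus-first-order (or immediate) release curves,
  back-converted to the raw sampled concentrations a fixed-volume
  replacement assay would record;
* one-compartment oral-absorption PK profiles with lognormal
  between-animal variability, destructively sampled (independent animals
  per time point).

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doe import DesignMatrix
from .release_pk import ConcentrationTimeProfile, ReleaseExperiment
from .surface import ResponseSet, _expand, model_terms

__all__ = [
    "SurfaceTruth",
    "PkTruth",
    "gen_ccd_responses",
    "gen_pk_profile",
    "gen_release_curve",
    "one_compartment_conc",
    "one_compartment_auc_inf",
    "one_compartment_auc",
]


@dataclass(frozen=True)
class SurfaceTruth:
    """Ground-truth polynomial surfaces and replicate noise for simulation.

    ``coefficients`` maps response name -> actual-unit coefficient vector
    over ``model_terms(k, model_class)`` (one model class for all
    responses); ``noise_sd`` maps response -> analytical-replicate SD in
    response units.
    """

    model_class: str
    coefficients: Mapping[str, Sequence[float]]
    noise_sd: Mapping[str, float]
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for r, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise SD for {r!r} must be nonnegative")
        missing = set(self.coefficients) - set(self.noise_sd)
        if missing:
            raise ValueError(f"noise_sd missing for responses: {sorted(missing)}")

    def surface_values(self, design: DesignMatrix, response: str) -> np.ndarray:
        terms = model_terms(design.k, self.model_class)
        beta = np.asarray(self.coefficients[response], dtype=float)
        if len(beta) != len(terms):
            raise ValueError(
                f"response {response!r}: {len(beta)} coefficients for "
                f"{len(terms)} {self.model_class} terms")
        return _expand(design.actual(), terms) @ beta


def gen_ccd_responses(design: DesignMatrix, truth: SurfaceTruth,
                      seed: int | None = None) -> ResponseSet:
    """Simulate replicate measurements on every design run.

    Each run's replicates are the true surface value plus iid Gaussian
    noise; the returned :class:`ResponseSet` carries the replicate mean,
    SD (ddof=1 when possible) and count, matching how formulation studies
    tabulate analytical triplicates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for response in truth.coefficients:
        mu = truth.surface_values(design, response)
        sd = float(truth.noise_sd[response])
        reps = mu[:, None] + rng.normal(0.0, sd, size=(len(mu), truth.n_replicates))
        means = reps.mean(axis=1)
        sds = reps.std(axis=1, ddof=1) if truth.n_replicates > 1 else np.zeros(len(mu))
        for run_id, m, s in zip(design.runs["run_id"], means, sds):
            rows.append((run_id, response, float(m), float(s), truth.n_replicates))
    return ResponseSet(pd.DataFrame(rows, columns=list(ResponseSet.REQUIRED)))


# ---------------------------------------------------------------------------
# one-compartment oral-absorption PK


def one_compartment_conc(t, dose: float, f: float, v: float, ka: float, ke: float):
    """C(t) = (F·D·ka / (V·(ka−ke))) · (e^{−ke t} − e^{−ka t})."""
    if ka == ke:
        raise ValueError("ka must differ from ke (flip-flop limit not supported)")
    t = np.asarray(t, dtype=float)
    c = (f * dose * ka) / (v * (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
    return float(c) if c.ndim == 0 else c


def one_compartment_auc_inf(dose: float, f: float, v: float, ke: float) -> float:
    """Closed-form AUC from zero to infinity, F·D/(V·ke)."""
    return f * dose / (v * ke)


def one_compartment_auc(t_end: float, dose: float, f: float, v: float,
                        ka: float, ke: float) -> float:
    """Closed-form AUC from 0 to ``t_end`` by direct integration."""
    if ka == ke:
        raise ValueError("ka must differ from ke")
    pref = f * dose * ka / (v * (ka - ke))
    return pref * ((1 - np.exp(-ke * t_end)) / ke - (1 - np.exp(-ka * t_end)) / ka)


@dataclass(frozen=True)
class PkTruth:
    """Ground truth for a destructively sampled single-dose oral PK study.

    Defaults mirror a mouse study design: samples at 0.5, 1, 2, 4, 8 and
    24 h post-dose with 3 animals per time point, each time point an
    independent animal group.
    """

    dose_mg_per_kg: float
    f: float
    v_l_per_kg: float
    ka_per_h: float
    ke_per_h: float
    cv: float = 0.2
    times_h: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 24.0)
    n_per_time: int = 3

    def __post_init__(self) -> None:
        if self.ka_per_h == self.ke_per_h:
            raise ValueError("ka must differ from ke")
        for name in ("dose_mg_per_kg", "v_l_per_kg", "ka_per_h", "ke_per_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.f <= 1):
            raise ValueError("bioavailability f must lie in (0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.n_per_time < 1:
            raise ValueError("n_per_time must be >= 1")
        if np.any(np.diff(self.times_h) <= 0) or self.times_h[0] <= 0:
            raise ValueError("sampling times must be positive and increasing")

    def mean_curve(self, t) -> np.ndarray:
        return one_compartment_conc(t, self.dose_mg_per_kg, self.f,
                                    self.v_l_per_kg, self.ka_per_h, self.ke_per_h)


def gen_pk_profile(truth: PkTruth, seed: int | None = None) -> ConcentrationTimeProfile:
    """Simulate a naive-pooled mean profile from destructive sampling.

    Each animal's concentration is the model value perturbed by a
    mean-one lognormal factor with coefficient of variation ``cv``
    (positive-valued biological noise); per-time means and SEMs are pooled
    across the ``n_per_time`` animals.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(truth.times_h, dtype=float)
    mu = truth.mean_curve(t)
    if truth.cv > 0:
        sigma2 = np.log(1.0 + truth.cv**2)
        factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2),
                                size=(truth.n_per_time, len(t)))
    else:
        factors = np.ones((truth.n_per_time, len(t)))
    animals = mu[None, :] * factors
    means = animals.mean(axis=0)
    sems = (animals.std(axis=0, ddof=1) / np.sqrt(truth.n_per_time)
            if truth.n_per_time > 1 else np.zeros(len(t)))
    return ConcentrationTimeProfile(
        times_h=t, mean_mg_per_l=means, sem_mg_per_l=sems,
        n_subjects=np.full(len(t), truth.n_per_time, dtype=float))


# ---------------------------------------------------------------------------
# release curves


def gen_release_curve(kind: str,
                      times_h: Sequence[float] = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0),
                      burst_fraction: float = 0.3,
                      rate_per_h: float = 0.5,
                      t_complete_h: float = 2.0,
                      dose_mg: float = 5.0,
                      v_total_ml: float = 10.0,
                      v_sample_ml: float = 0.5,
                      noise_cv: float = 0.0,
                      seed: int | None = None) -> ReleaseExperiment:
    """Simulate the raw sampled concentrations of a release assay.

    ``kind="burst_plus_first_order"`` uses the biphasic released fraction
    f(t) = b + (1-b)(1 - e^{-k t}) (initial burst ``b`` from
    surface-associated drug, first-order release from the matrix);
    ``kind="immediate"`` releases everything by ``t_complete_h``.  The true
    in-vessel concentrations are back-converted to the sequence of sampled
    concentrations that fixed-volume replacement sampling would record, so
    applying the replacement correction recovers f(t) exactly when
    ``noise_cv`` is 0.
    """
    times = np.asarray(times_h, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if kind == "burst_plus_first_order":
        if not (0 <= burst_fraction <= 1):
            raise ValueError("burst fraction must lie in [0, 1]")
        if rate_per_h < 0:
            raise ValueError("rate must be nonnegative")
        frac = burst_fraction + (1 - burst_fraction) * (1 - np.exp(-rate_per_h * times))
    elif kind == "immediate":
        frac = np.where(times >= t_complete_h, 1.0, times / t_complete_h)
    else:
        raise ValueError(f"unknown release kind {kind!r}")

    # invert the replacement correction: find sampled C_n such that
    # C_n + (Vs/Vt)·sum_{i<n} C_i = f_n·dose/Vt
    ratio = v_sample_ml / v_total_ml
    target = frac * dose_mg / v_total_ml
    sampled = np.empty_like(target)
    running = 0.0
    for i, tgt in enumerate(target):
        sampled[i] = tgt - ratio * running
        running += sampled[i]
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sampled = sampled * rng.lognormal(
            mean=-np.log(1 + noise_cv**2) / 2,
            sigma=np.sqrt(np.log(1 + noise_cv**2)), size=len(sampled))
    sampled = np.maximum(sampled, 0.0)
    return ReleaseExperiment(times_h=times, conc_mg_per_ml=sampled,
                             v_total_ml=v_total_ml, v_sample_ml=v_sample_ml,
                             dose_mg=dose_mg)
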