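"""Release-profile processing and non-compartmental pharmacokinetics.

``cumulative_release`` converts raw in-vessel concentrations from a
fixed-volume replacement sampling scheme (each withdrawn sample replaced
with fresh medium) into cumulative percent released, using the standard
additive running-sum correction

    C'_n = C_n + (V_sample / V_total) * sum_{i<n} C_i.

``nca`` computes Cmax, Tmax and the linear-trapezoid AUC from a mean
plasma concentration–time profile (naive pooling across destructively
sampled animals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ReleaseExperiment",
    "ConcentrationTimeProfile",
    "NCAResult",
    "cumulative_release",
    "nca",
    "profile_fold_change",
]


@dataclass
class ReleaseExperiment:
    """Raw data from one sequential-sampling release assay."""

    times_h: np.ndarray
    conc_mg_per_ml: np.ndarray
    v_total_ml: float
    v_sample_ml: float
    dose_mg: float

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.conc_mg_per_ml = np.asarray(self.conc_mg_per_ml, dtype=float)
        if self.times_h.shape != self.conc_mg_per_ml.shape:
            raise ValueError("times and concentrations must have the same length")
        if len(self.times_h) and np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0 < self.v_sample_ml < self.v_total_ml):
            raise ValueError("need 0 < sample volume < vessel volume")
        if self.dose_mg <= 0:
            raise ValueError("dose must be positive")
        if np.any(self.conc_mg_per_ml < 0):
            raise ValueError("concentrations must be nonnegative")

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "time_h": self.times_h,
            "concentration_mg_per_ml": self.conc_mg_per_ml,
        }).to_csv(path, index=False, float_format="%.12g")


def cumulative_release(exp: ReleaseExperiment,
                       over_range_tolerance: float = 0.5) -> pd.DataFrame:
    """Cumulative percent released at each sampling time.

    Returns a frame with the raw concentration, the replacement-corrected
    concentration, cumulative percent of dose released, and a boolean
    ``over_range`` flagging (not clamping) values above
    ``100 + over_range_tolerance`` percent — a sign of assay or input
    inconsistency.
    """
    C = exp.conc_mg_per_ml
    ratio = exp.v_sample_ml / exp.v_total_ml
    prior = np.concatenate(([0.0], np.cumsum(C)[:-1]))
    corrected = C + ratio * prior
    pct = corrected * exp.v_total_ml / exp.dose_mg * 100.0
    return pd.DataFrame({
        "time_h": exp.times_h,
        "concentration_mg_per_ml": C,
        "corrected_mg_per_ml": corrected,
        "cumulative_release_pct": pct,
        "over_range": pct > 100.0 + over_range_tolerance,
    })


@dataclass
class ConcentrationTimeProfile:
    """Mean plasma concentration vs time after a single dose."""

    times_h: np.ndarray
    mean_mg_per_l: np.ndarray
    sem_mg_per_l: np.ndarray | None = None
    n_subjects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.mean_mg_per_l = np.asarray(self.mean_mg_per_l, dtype=float)
        if self.times_h.shape != self.mean_mg_per_l.shape:
            raise ValueError("times and concentrations must have the same length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.mean_mg_per_l < 0):
            raise ValueError("concentrations must be nonnegative")
        for name in ("sem_mg_per_l", "n_subjects"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times_h.shape:
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, v)

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"time_h": self.times_h, "mean_conc_mg_per_L": self.mean_mg_per_l})
        if self.sem_mg_per_l is not None:
            df["sem"] = self.sem_mg_per_l
        if self.n_subjects is not None:
            df["n"] = self.n_subjects
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "ConcentrationTimeProfile":
        df = pd.read_csv(path)
        need = {"time_h", "mean_conc_mg_per_L"}
        if not need <= set(df.columns):
            raise ValueError(f"PK CSV needs columns {sorted(need)}")
        return cls(
            df["time_h"], df["mean_conc_mg_per_L"],
            df["sem"] if "sem" in df.columns else None,
            df["n"] if "n" in df.columns else None,
        )


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental summary of a concentration-time profile."""

    cmax_mg_per_l: float
    tmax_h: float
    auc_mg_h_per_l: float
    auc_interval_h: tuple[float, float] = field(default=(0.0, 24.0))


def nca(profile: ConcentrationTimeProfile, assume_zero_at_dose: bool = True) -> NCAResult:
    """Cmax, Tmax and linear-trapezoid AUC from observed mean concentrations.

    Cmax/Tmax come from the observed points (earliest time on ties).  The
    AUC runs from dose time to the last observation; with
    ``assume_zero_at_dose`` (default, appropriate for extravascular dosing
    where the first sample is after absorption begins) a C(0) = 0 point is
    prepended unless t = 0 was observed.
    """
    t = profile.times_h
    c = profile.mean_mg_per_l
    if len(t) < 2:
        raise ValueError("need at least two time points for NCA")
    imax = int(np.argmax(c))  # argmax returns the earliest index on ties
    if assume_zero_at_dose and t[0] > 0:
        t = np.concatenate(([0.0], t))
        c = np.concatenate(([0.0], c))
    auc = float(np.trapezoid(c, t))
    return NCAResult(
        cmax_mg_per_l=float(profile.mean_mg_per_l[imax]),
        tmax_h=float(profile.times_h[imax]),
        auc_mg_h_per_l=auc,
        auc_interval_h=(float(t[0]), float(t[-1])),
    )


def profile_fold_change(a: NCAResult, b: NCAResult) -> pd.DataFrame:
    """Per-parameter ratio a/b and percent increase 100*(a-b)/b."""
    pairs = {
        "cmax_mg_per_l": (a.cmax_mg_per_l, b.cmax_mg_per_l),
        "tmax_h": (a.tmax_h, b.tmax_h),
        "auc_mg_h_per_l": (a.auc_mg_h_per_l, b.auc_mg_h_per_l),
    }
    rows = []
    for name, (va, vb) in pairs.items():
        if vb <= 0:
            raise ZeroDivisionError(f"reference {name} must be positive")
        rows.append((name, va, vb, va / vb, 100.0 * (va - vb) / vb))
    return pd.DataFrame(
        rows, columns=["parameter", "value", "reference", "ratio", "percent_increase"]
    ).set_index("parameter")
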