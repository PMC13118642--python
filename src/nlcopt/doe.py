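"""Central composite designs (CCD) for response-surface studies.

A CCD for k factors augments the 2^k two-level factorial with 2k axial
("star") points at coded distance ±alpha from the center and n_center
replicated center runs.  With alpha = (2^k)^(1/4) the design is rotatable:
the prediction variance of a full second-order model depends only on the
distance from the design center.

Factor levels are handled in two unit systems throughout the package:

* *coded* units, where the center is 0 and the factorial levels are ±1;
* *actual* units (here milligrams), related by ``actual = center + coded*step``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignSpec",
    "DesignMatrix",
    "rotatable_alpha",
    "build_ccd",
    "code",
    "decode",
    "POINT_TYPES",
]

POINT_TYPES = ("factorial", "axial", "center")


@dataclass(frozen=True)
class Factor:
    """One controllable formulation factor.

    Parameters
    ----------
    name
        Identifier used for design-matrix columns (e.g. ``"lipid"``).
    unit
        Physical unit of the actual levels (e.g. ``"mg"``).
    center
        Actual value at coded level 0.
    step
        Actual distance between coded 0 and coded ±1; must be positive.
    """

    name: str
    unit: str
    center: float
    step: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.center):
            raise ValueError(f"factor {self.name!r}: center must be finite")
        if not (np.isfinite(self.step) and self.step > 0):
            raise ValueError(f"factor {self.name!r}: step must be positive")

    def code(self, actual: float) -> float:
        return (np.asarray(actual, dtype=float) - self.center) / self.step

    def decode(self, coded: float) -> float:
        return self.center + np.asarray(coded, dtype=float) * self.step


def code(value, factor: Factor):
    """Map an actual-unit value to coded units for ``factor``."""
    return factor.code(value)


def decode(coded, factor: Factor):
    """Map a coded value back to actual units for ``factor``."""
    return factor.decode(coded)


def rotatable_alpha(k: int) -> float:
    """Axial distance making a k-factor CCD rotatable, (2^k)^(1/4)."""
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool) or k < 1:
        raise ValueError(f"k must be a positive integer, got {k!r}")
    return float((2.0**k) ** 0.25)


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a CCD: factors, center replication and axial distance.

    ``alpha`` is either the string ``"rotatable"`` (resolved to
    ``(2^k)^(1/4)``) or an explicit positive number >= 1.
    """

    factors: tuple[Factor, ...]
    n_center: int = 5
    alpha: float | str = "rotatable"

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", tuple(self.factors))
        if len(self.factors) < 2:
            raise ValueError("a CCD needs at least 2 factors")
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate factor names: {names}")
        if self.n_center < 1:
            raise ValueError("n_center must be >= 1")
        if self.resolved_alpha() < 1:
            raise ValueError("alpha must resolve to a value >= 1")

    @property
    def k(self) -> int:
        return len(self.factors)

    def resolved_alpha(self) -> float:
        if isinstance(self.alpha, str):
            if self.alpha != "rotatable":
                raise ValueError(f"unknown alpha sentinel {self.alpha!r}")
            return rotatable_alpha(self.k)
        a = float(self.alpha)
        if not np.isfinite(a):
            raise ValueError("alpha must be finite")
        return a

    @property
    def n_runs(self) -> int:
        return 2**self.k + 2 * self.k + self.n_center


@dataclass
class DesignMatrix:
    """A realized design: one row per run, coded and actual factor levels.

    ``runs`` holds columns ``run_id``, ``point_type`` and, per factor,
    ``<name>_coded`` and ``<name>_actual``.
    """

    factors: tuple[Factor, ...]
    runs: pd.DataFrame
    alpha: float
    seed: int | None = field(default=None)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        self.validate()

    # -- accessors ---------------------------------------------------------

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.factors)

    def coded(self) -> np.ndarray:
        """(n_runs, k) array of coded levels in run order."""
        cols = [f"{n}_coded" for n in self.factor_names]
        return self.runs[cols].to_numpy(dtype=float)

    def actual(self) -> np.ndarray:
        """(n_runs, k) array of actual-unit levels in run order."""
        cols = [f"{n}_actual" for n in self.factor_names]
        return self.runs[cols].to_numpy(dtype=float)

    def point_type_counts(self) -> dict[str, int]:
        counts = self.runs["point_type"].value_counts().to_dict()
        return {t: int(counts.get(t, 0)) for t in POINT_TYPES}

    # -- validation --------------------------------------------------------

    def validate(self, rtol: float = 1e-9) -> None:
        required = {"run_id", "point_type"}
        for n in self.factor_names:
            required |= {f"{n}_coded", f"{n}_actual"}
        missing = required - set(self.runs.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        if self.runs["run_id"].duplicated().any():
            dup = self.runs.loc[self.runs["run_id"].duplicated(), "run_id"].tolist()
            raise ValueError(f"duplicate run_id values: {dup}")
        bad = set(self.runs["point_type"]) - set(POINT_TYPES)
        if bad:
            raise ValueError(f"unknown point types: {sorted(bad)}")
        for f in self.factors:
            c = self.runs[f"{f.name}_coded"].to_numpy(dtype=float)
            a = self.runs[f"{f.name}_actual"].to_numpy(dtype=float)
            expect = f.decode(c)
            scale = max(abs(f.center), f.step)
            if np.max(np.abs(a - expect)) > rtol * scale:
                raise ValueError(
                    f"factor {f.name!r}: actual levels inconsistent with "
                    f"coded levels (max deviation "
                    f"{np.max(np.abs(a - expect)):.3g} {f.unit})"
                )

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.runs.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_frame(cls, runs: pd.DataFrame, factors: Sequence[Factor],
                   alpha: float | None = None, rtol: float = 1e-9) -> "DesignMatrix":
        if alpha is None:
            coded = np.abs(runs[[f"{f.name}_coded" for f in factors]].to_numpy(dtype=float))
            alpha = float(coded.max()) if len(runs) else 1.0
        dm = cls.__new__(cls)
        dm.factors = tuple(factors)
        dm.runs = runs
        dm.alpha = float(alpha)
        dm.seed = None
        dm.validate(rtol=rtol)
        return dm

    @classmethod
    def from_csv(cls, path, factors: Sequence[Factor], alpha: float | None = None,
                 rtol: float = 1e-9) -> "DesignMatrix":
        return cls.from_frame(pd.read_csv(path), factors, alpha=alpha, rtol=rtol)


def build_ccd(spec: DesignSpec, seed: int | None = None) -> DesignMatrix:
    """Construct the CCD run table for ``spec``.

    Runs are laid out in canonical order (factorial block in binary order,
    axial block factor by factor with -alpha before +alpha, then the center
    replicates).  Passing a ``seed`` randomizes the run order
    reproducibly; ``std_order`` keeps the canonical index either way.
    """
    k = spec.k
    alpha = spec.resolved_alpha()

    blocks: list[tuple[str, tuple[float, ...]]] = []
    for levels in itertools.product((-1.0, 1.0), repeat=k):
        blocks.append(("factorial", levels))
    for j in range(k):
        for sign in (-1.0, 1.0):
            levels = tuple(sign * alpha if i == j else 0.0 for i in range(k))
            blocks.append(("axial", levels))
    for _ in range(spec.n_center):
        blocks.append(("center", (0.0,) * k))

    order = np.arange(len(blocks))
    if seed is not None:
        order = np.random.default_rng(seed).permutation(order)

    rows = []
    for run_id, idx in enumerate(order, start=1):
        ptype, coded = blocks[idx]
        row: dict[str, object] = {
            "run_id": run_id,
            "std_order": int(idx) + 1,
            "point_type": ptype,
        }
        for f, c in zip(spec.factors, coded):
            row[f"{f.name}_coded"] = c
            row[f"{f.name}_actual"] = f.decode(c)
        rows.append(row)
    runs = pd.DataFrame(rows)
    return DesignMatrix(factors=spec.factors, runs=runs, alpha=alpha, seed=seed)
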