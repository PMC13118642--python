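"""Readers and writers for the tabular formats used across the package."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .doe import DesignMatrix, Factor
from .surface import ResponseSet

__all__ = ["SchemaError", "load_design_table", "write_design_table"]


class SchemaError(ValueError):
    """A tabular input does not match the expected schema."""


def _require_numeric(df: pd.DataFrame, col: str) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() & df[col].notna()]
    if len(bad):
        raise SchemaError(f"non-numeric value in column {col!r}, row {bad[0] + 2} "
                          f"(value {df.loc[bad[0], col]!r})")
    if vals.isna().any():
        raise SchemaError(f"missing value in column {col!r}, "
                          f"row {int(df.index[vals.isna()][0]) + 2}")
    return vals.to_numpy(dtype=float)


def load_design_table(path, factors: Sequence[Factor]
                      ) -> tuple[DesignMatrix, ResponseSet]:
    """Read a combined design/response CSV.

    Expected columns: ``run_id``, ``point_type``, per factor
    ``<name>_coded`` and ``<name>_actual``, and per response
    ``<response>_mean`` with optional ``<response>_sd`` and a shared
    replicate count column ``n``.  Column order is irrelevant.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    df = df.reset_index(drop=True)

    required = ["run_id", "point_type"]
    for f in factors:
        required += [f"{f.name}_coded", f"{f.name}_actual"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    if df["run_id"].duplicated().any():
        dup = df.loc[df["run_id"].duplicated(), "run_id"].tolist()
        raise SchemaError(f"{path}: duplicate run_id values {dup}")

    for f in factors:
        _require_numeric(df, f"{f.name}_coded")
        _require_numeric(df, f"{f.name}_actual")

    resp_names = [c[:-5] for c in df.columns if c.endswith("_mean")]
    if not resp_names:
        raise SchemaError(f"{path}: no '<response>_mean' columns found")
    n_col = _require_numeric(df, "n") if "n" in df.columns else np.ones(len(df))

    rows = []
    for resp in resp_names:
        means = _require_numeric(df, f"{resp}_mean")
        sds = (_require_numeric(df, f"{resp}_sd")
               if f"{resp}_sd" in df.columns else np.zeros(len(df)))
        for rid, m, s, n in zip(df["run_id"], means, sds, n_col):
            rows.append((rid, resp, m, s, int(n)))
    responses = ResponseSet(pd.DataFrame(rows, columns=list(ResponseSet.REQUIRED)))

    design_cols = required
    design = DesignMatrix.from_frame(df[design_cols].copy(), factors)
    return design, responses


def write_design_table(path, design: DesignMatrix, responses: ResponseSet) -> None:
    """Write the combined wide-format design/response CSV read by
    :func:`load_design_table`."""
    df = design.runs.copy()
    wide = responses.table.pivot(index="run_id", columns="response")
    out = df.set_index("run_id")
    for resp in responses.responses:
        out[f"{resp}_mean"] = wide[("mean", resp)]
        out[f"{resp}_sd"] = wide[("sd", resp)]
    n = responses.table.pivot(index="run_id", columns="response", values="n")
    out["n"] = n.iloc[:, 0]
    out.reset_index().to_csv(path, index=False, float_format="%.12g")
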