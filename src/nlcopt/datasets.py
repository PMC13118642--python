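"""Packaged example data: the 13-run CCD formulation study and its PK summary.

The CCD fixture is the published design/response matrix of a two-factor
nanostructured-lipid-carrier optimization (solid lipid and surfactant
amounts in mg; responses: particle size in nm, polydispersity index, and
zeta potential in mV, each the mean ± SD of three analytical replicates).
The PK fixture holds the reported non-compartmental parameters (Cmax,
Tmax, AUC 0–24 h) for stiripentol and cannabidiol from the optimized
formulation and the corresponding commercial products.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .doe import DesignMatrix, Factor
from .release_pk import NCAResult
from .surface import ResponseSet

__all__ = [
    "study_factors",
    "ccd_study",
    "pk_parameters",
    "pk_result",
    "RESPONSES",
    "MEASURED_OPTIMUM",
]

#: canonical response names of the formulation study, in report order
RESPONSES = ("particle_size", "pdi", "zeta_potential")

#: values measured on the optimized formulation (used for validation records)
MEASURED_OPTIMUM = {"particle_size": 175.3, "pdi": 0.232, "zeta_potential": -8.35}


def study_factors() -> tuple[Factor, Factor]:
    """The two formulation factors: solid lipid and surfactant amount (mg)."""
    return (
        Factor("lipid", "mg", center=300.0, step=100.0),
        Factor("surfactant", "mg", center=400.0, step=200.0),
    )


def _data_path(name: str):
    return resources.files("nlcopt").joinpath("data").joinpath(name)


def ccd_study() -> tuple[DesignMatrix, ResponseSet]:
    """The packaged 13-run CCD design with its measured responses."""
    from .io import load_design_table

    with resources.as_file(_data_path("ccd_study.csv")) as p:
        return load_design_table(p, study_factors())


def pk_parameters() -> pd.DataFrame:
    """Reported NCA parameters per drug and product."""
    with resources.as_file(_data_path("pk_parameters.csv")) as p:
        return pd.read_csv(p)


def pk_result(drug: str, product: str) -> NCAResult:
    """One row of :func:`pk_parameters` as an :class:`NCAResult`."""
    df = pk_parameters()
    row = df[(df["drug"] == drug) & (df["product"] == product)]
    if row.empty:
        raise KeyError(f"no PK entry for drug={drug!r}, product={product!r}")
    r = row.iloc[0]
    return NCAResult(
        cmax_mg_per_l=float(r["cmax_mg_per_l"]),
        tmax_h=float(r["tmax_h"]),
        auc_mg_h_per_l=float(r["auc_0_24_mg_h_per_l"]),
        auc_interval_h=(0.0, 24.0),
    )
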