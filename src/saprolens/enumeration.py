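"""Counting-chamber enumeration.

Converts Sedgwick-Rafter chamber observations to concentrations. The
chamber holds 1 mL over a 1000-square grid; counting ``N`` of the
squares in a ``V_C`` mL concentrate prepared from a ``V_T`` mL grab
gives

    individuals per mL = C * V_C * 1000 / (V_T * N)

with ``C`` the organisms counted. Concentrations are stored per litre
downstream, so the per-mL result is scaled by 1000 at ingestion. A zero
count is reported as 0 (no detection-limit censoring).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .types import CommunityMatrix, SaprolensError

__all__ = [
    "CountObservation",
    "concentration_per_ml",
    "concentration_per_litre",
    "count_sheet_to_matrix",
]


@dataclass(frozen=True)
class CountObservation:
    """One chamber count.

    Parameters
    ----------
    c : int
        Organisms counted (non-negative).
    n_squares : int
        Grid squares examined, ``1 <= n_squares <= total_squares``.
    v_concentrate_ml : float
        Final volume of the concentrated sample (mL).
    v_total_ml : float
        Volume of the initial grab sample (mL).
    total_squares : int
        Squares in the chamber grid; 1000 for a Sedgwick-Rafter cell,
        overridable for other chamber geometries.
    """

    c: int
    n_squares: int
    v_concentrate_ml: float
    v_total_ml: float
    total_squares: int = 1000

    def __post_init__(self) -> None:
        if self.c < 0:
            raise SaprolensError("count C must be non-negative")
        if not (1 <= self.n_squares <= self.total_squares):
            raise SaprolensError(
                f"n_squares must be in [1, {self.total_squares}], got {self.n_squares}"
            )
        if not self.v_total_ml > 0:
            raise SaprolensError("grab volume V_T must be positive")
        if not self.v_concentrate_ml > 0:
            raise SaprolensError("concentrate volume V_C must be positive")
        if self.v_concentrate_ml > self.v_total_ml:
            raise SaprolensError("concentrate volume cannot exceed grab volume")


def concentration_per_ml(obs: CountObservation) -> float:
    """Individuals per mL of the original grab implied by one count."""
    return (obs.c * obs.v_concentrate_ml * obs.total_squares) / (
        obs.v_total_ml * obs.n_squares
    )


def concentration_per_litre(c_ml: float) -> float:
    """Convert individuals per mL to individuals per litre."""
    if c_ml < 0:
        raise SaprolensError("concentration must be non-negative")
    return 1000.0 * c_ml


#: Required columns of a count-sheet table.
COUNT_SHEET_COLUMNS = ("sample_id", "taxon_id", "C", "N", "V_C", "V_T")


def count_sheet_to_matrix(sheet: pd.DataFrame, total_squares: int = 1000) -> CommunityMatrix:
    """Turn a long-format count sheet into a community matrix (ind L^-1).

    ``sheet`` needs columns ``sample_id, taxon_id, C, N, V_C, V_T``; one
    row per (sample, taxon) observation. Taxa never observed in a sample
    appear as 0.
    """
    missing = [c for c in COUNT_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise SaprolensError(f"count sheet lacks columns: {missing}")
    if sheet.duplicated(["sample_id", "taxon_id"]).any():
        raise SaprolensError("duplicate (sample_id, taxon_id) rows in count sheet")
    conc = []
    for row in sheet.itertuples(index=False):
        obs = CountObservation(
            c=int(row.C),
            n_squares=int(row.N),
            v_concentrate_ml=float(row.V_C),
            v_total_ml=float(row.V_T),
            total_squares=total_squares,
        )
        conc.append(concentration_per_litre(concentration_per_ml(obs)))
    long = sheet[["sample_id", "taxon_id"]].copy()
    long["value"] = conc
    wide = (
        long.pivot(index="sample_id", columns="taxon_id", values="value")
        .fillna(0.0)
        .rename_axis(index=None, columns=None)
    )
    # keep first-appearance order rather than alphabetical
    wide = wide.loc[
        pd.unique(sheet["sample_id"]).tolist(), pd.unique(sheet["taxon_id"]).tolist()
    ]
    return CommunityMatrix(wide, units="ind_per_l")
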