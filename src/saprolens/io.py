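"""Delimited-table readers/writers, config loading, and bundled fixtures.

All matrices and registries travel as CSV/TSV with a header row; the
saprobic valence table and class bands are a YAML config. The bundled
fixtures transcribe the source study's tables:

- ``table1``: the seven-band saprobic classification scheme;
- ``table2_site_means``: per-site mean +/- SD of 32 water-quality
  variables;
- ``table4_site_means``: 54 taxa x 6 sites mean abundance (ind L^-1)
  and biomass (ug L^-1) matrices;
- ``table4_averages``: the 54-taxon campaign-average abundance and
  biomass columns;
- ``trait_registry``: phylum, saprobity code and feeding guild per
  taxon, with geometric shape classes where stated.

The typeset species table leaves blanks for absences and the extracted
text keeps only cell order, so some per-site placements were
reconstructed from the study's own per-site totals; such rows carry
``site_assignment == "reconstructed"`` in the underlying data file.
"""
from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    ClassBand,
    CommunityMatrix,
    EnvironmentMatrix,
    MatrixError,
    RegistryError,
    SaprobicValenceTable,
    SaprolensError,
    TaxonRecord,
    TraitRegistry,
)

__all__ = [
    "read_trait_registry",
    "read_community_matrix",
    "write_community_matrix",
    "read_environment_matrix",
    "load_valence_table",
    "default_valence_table",
    "load_study_fixture",
    "write_summary_report",
]

_SITES = ["I", "II", "III", "IV", "V", "VI"]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return str(value)


def _opt_float(value) -> float | None:
    if value is None or value == "":
        return None
    value = float(value)
    return None if np.isnan(value) else value


def read_trait_registry(path) -> TraitRegistry:
    """Read a taxon trait registry from CSV/TSV.

    Required columns: ``taxon_id``, ``name``, ``phylum``; optional:
    ``shape``, ``length_um``, ``width_um``, ``saprobity_code``,
    ``feeding_guild`` (blank allowed). Unknown shape/phylum tokens,
    duplicate ids, and length < width are rejected.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"taxon_id", "name", "phylum"}
    if not required.issubset(df.columns):
        raise RegistryError(f"registry needs columns {sorted(required)}")
    records = []
    for row in df.to_dict("records"):
        records.append(
            TaxonRecord(
                taxon_id=str(row["taxon_id"]),
                name=_opt_str(row.get("name")) or "",
                phylum=str(row["phylum"]),
                shape=_opt_str(row.get("shape")),
                length_um=_opt_float(_opt_str(row.get("length_um"))),
                width_um=_opt_float(_opt_str(row.get("width_um"))),
                saprobity_code=_opt_str(row.get("saprobity_code")),
                feeding_guild=_opt_str(row.get("feeding_guild")),
            )
        )
    return TraitRegistry(records)


def read_community_matrix(
    path,
    orientation: str = "samples-as-rows",
    sample_meta: pd.DataFrame | None = None,
    units: str = "ind_per_l",
) -> CommunityMatrix:
    """Read a community matrix from CSV/TSV.

    First column holds labels, header holds the other axis; the matrix
    is normalised internally to samples-as-rows regardless of
    ``orientation`` (``"samples-as-rows"`` or ``"taxa-as-rows"``).
    Negative or non-numeric cells are rejected.
    """
    if orientation not in {"samples-as-rows", "taxa-as-rows"}:
        raise SaprolensError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_sep(path), index_col=0,
                     float_precision="round_trip")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise MatrixError(f"non-numeric cell in {path}: {exc}") from None
    if orientation == "taxa-as-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CommunityMatrix(df, sample_meta=sample_meta, units=units)


def write_community_matrix(matrix: CommunityMatrix, path) -> None:
    """Write a community matrix (samples-as-rows) at full precision."""
    out = matrix.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep(path), float_format="%.17g")


def read_environment_matrix(path) -> EnvironmentMatrix:
    """Read a samples x variables table; ``var (unit)`` headers split out."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0,
                     float_precision="round_trip")
    units = {}
    renames = {}
    for col in df.columns:
        if "(" in col and col.endswith(")"):
            name, unit = col[:-1].split("(", 1)
            renames[col] = name.strip()
            units[name.strip()] = unit.strip()
        else:
            units[col] = ""
    df = df.rename(columns=renames).astype(float)
    df.index = df.index.astype(str)
    return EnvironmentMatrix(df, units)


def _bands_from_config(raw) -> list[ClassBand]:
    return [
        ClassBand(float(lo), float(hi), str(level), str(degree), str(qc))
        for lo, hi, level, degree, qc in raw
    ]


def load_valence_table(path) -> SaprobicValenceTable:
    """Load a saprobic-system YAML config (valences + class bands)."""
    with open(path) as f:
        cfg = yaml.safe_load(f)
    code_to_s = {str(k): float(v) for k, v in cfg["valences"].items()}
    table = SaprobicValenceTable(code_to_s, _bands_from_config(cfg["class_bands"]))
    table.species_overrides = {
        str(k): float(v) for k, v in (cfg.get("species_overrides") or {}).items()
    }
    return table


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("saprolens") / "data" / name)


def default_valence_table() -> SaprobicValenceTable:
    """The bundled generic Pantle-Buck valence table and band scheme."""
    return load_valence_table(_data_path("saprobic_system.yml"))


def _community_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("protozoa_community_table.csv"))


FIXTURES = (
    "table1",
    "table2_site_means",
    "table4_site_means",
    "table4_averages",
    "trait_registry",
)


def load_study_fixture(name: str):
    """Return one of the bundled study-table transcriptions.

    - ``table1`` -> :class:`SaprobicValenceTable` (band scheme + generic
      code valences);
    - ``table2_site_means`` -> DataFrame of per-site environmental
      means/SDs (variables as rows);
    - ``table4_site_means`` -> dict with ``abundance`` and ``biomass``
      :class:`CommunityMatrix` objects (6 site-mean samples x 54 taxa);
    - ``table4_averages`` -> DataFrame indexed by taxon_id with
      campaign-average ``abundance`` (ind L^-1) and ``biomass``
      (ug L^-1);
    - ``trait_registry`` -> :class:`TraitRegistry`.
    """
    if name == "table1":
        return default_valence_table()
    if name == "table2_site_means":
        return pd.read_csv(_data_path("env_site_summary.csv")).set_index("variable")
    if name == "trait_registry":
        return read_trait_registry(_data_path("trait_registry.csv"))
    df = _community_table().set_index("taxon_id")
    if name == "table4_averages":
        out = df[["name", "phylum", "abundance_avg", "biomass_avg"]].rename(
            columns={"abundance_avg": "abundance", "biomass_avg": "biomass"}
        )
        return out
    if name == "table4_site_means":
        meta = pd.DataFrame({"site": _SITES}, index=_SITES)
        result = {}
        for kind, units in (("abundance", "ind_per_l"), ("biomass", "ug_per_l")):
            mat = df[[f"{kind}_{s}" for s in _SITES]].T
            mat.index = _SITES
            result[kind] = CommunityMatrix(mat, sample_meta=meta, units=units)
        return result
    raise SaprolensError(f"unknown fixture {name!r}; choose from {FIXTURES}")


def write_summary_report(results, path) -> None:
    """Write a result table as CSV plus an aligned human-readable text file.

    ``results`` may be a DataFrame, a mapping, or a list of dataclasses
    (e.g. saprobity results). Output is bit-stable for identical inputs.
    An empty result set yields a header-only file.
    """
    import dataclasses

    if isinstance(results, pd.DataFrame):
        df = results.copy()
    elif isinstance(results, dict):
        df = pd.DataFrame(results)
    else:
        rows = [
            dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
            for r in results
        ]
        cols = list(rows[0]) if rows else ["sample_id", "value"]
        df = pd.DataFrame(rows, columns=cols)
    path = Path(path)
    df.to_csv(path, float_format="%.6g", index=isinstance(results, pd.DataFrame))
    with open(path.with_suffix(".txt"), "w") as f:
        f.write(df.to_string() + "\n")
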