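"""Pantle-Buck saprobic index and water-quality classification.

Each indicator taxon carries a saprobity code (``o``, ``b``, ``a``,
``p`` and transitional forms such as ``a-b``) that resolves to a numeric
valence S in [1, 4] via a :class:`~saprolens.types.SaprobicValenceTable`.
The saprobic index of a sample is the abundance-weighted mean valence

    SI = sum(S_i * h_i) / sum(h_i)

over classified taxa, and maps onto seven half-open bands from
oligosaprobic (class I, non-polluted) to polysaprobic (class IV).
Unclassified taxa are excluded; the classified fraction of total
abundance is always reported so users can judge how representative the
index is.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    CommunityMatrix,
    SaprobicValenceTable,
    SaprolensError,
    TraitRegistry,
)

__all__ = [
    "SaprobicResult",
    "resolve_valence",
    "saprobic_index",
    "classify_saprobic",
    "sample_saprobity",
    "campaign_saprobity",
]


@dataclass(frozen=True)
class SaprobicResult:
    """Saprobic index of one sample or group, with classification."""

    sample_id: str
    si: float
    n_classified_taxa: int
    classified_fraction_of_abundance: float
    level: str
    degree: str
    quality_class: str


def resolve_valence(code: str, table: SaprobicValenceTable) -> float:
    """Numeric valence S for a saprobity code (unknown codes raise)."""
    return table.resolve(code)


def saprobic_index(abundances, valences) -> float:
    """Abundance-weighted mean valence sum(S h) / sum(h)."""
    h = np.asarray(abundances, dtype=float)
    s = np.asarray(valences, dtype=float)
    if h.shape != s.shape:
        raise SaprolensError("abundance and valence vectors differ in length")
    if (h < 0).any():
        raise SaprolensError("negative abundance")
    total = h.sum()
    if total == 0:
        raise SaprolensError("saprobic index undefined: zero classified abundance")
    return float((s * h).sum() / total)


def classify_saprobic(si: float, table: SaprobicValenceTable):
    """(saprobic level, pollution degree, quality class) for an index value."""
    band = table.classify(si)
    return band.level, band.degree, band.quality_class


def _classified_columns(
    matrix: CommunityMatrix, registry: TraitRegistry, table: SaprobicValenceTable
) -> tuple[list[str], np.ndarray]:
    taxa, vals = [], []
    for taxon_id in matrix.taxon_ids:
        code = registry[taxon_id].saprobity_code
        if code:
            taxa.append(taxon_id)
            vals.append(table.resolve(code))
    return taxa, np.asarray(vals)


def _result(sample_id, h, s, total_abundance, table) -> SaprobicResult:
    si = saprobic_index(h, s)
    level, degree, qclass = classify_saprobic(si, table)
    frac = float(h.sum() / total_abundance) if total_abundance > 0 else 0.0
    return SaprobicResult(
        sample_id=str(sample_id),
        si=si,
        n_classified_taxa=int((h > 0).sum()),
        classified_fraction_of_abundance=frac,
        level=level,
        degree=degree,
        quality_class=qclass,
    )


def sample_saprobity(
    matrix: CommunityMatrix, registry: TraitRegistry, table: SaprobicValenceTable
) -> list[SaprobicResult]:
    """Per-sample saprobic index over the matrix's classified taxa."""
    taxa, vals = _classified_columns(matrix, registry, table)
    if not taxa:
        raise SaprolensError("no taxon in the matrix carries a saprobity code")
    sub = matrix.data[taxa].to_numpy()
    totals = matrix.data.sum(axis=1).to_numpy()
    return [
        _result(sid, sub[i], vals, totals[i], table)
        for i, sid in enumerate(matrix.sample_ids)
    ]


def campaign_saprobity(
    matrix: CommunityMatrix,
    registry: TraitRegistry,
    table: SaprobicValenceTable,
    group_by: str = "site",
    mode: str = "si_of_means",
) -> pd.DataFrame:
    """Per-group saprobic index with classification and coverage.

    Two aggregation modes (field software differs and sources rarely say
    which was used):

    - ``"si_of_means"``: SI computed on the group's mean abundance
      profile (one SI per group);
    - ``"mean_of_si"``: per-sample SI first, then the arithmetic group
      mean.

    Returns a DataFrame indexed by group with ``si``, classification
    fields, and coverage diagnostics.
    """
    if mode not in {"si_of_means", "mean_of_si"}:
        raise SaprolensError(f"unknown mode {mode!r}")
    labels = matrix.factor(group_by)
    taxa, vals = _classified_columns(matrix, registry, table)
    if not taxa:
        raise SaprolensError("no taxon in the matrix carries a saprobity code")
    rows = []
    for level, idx in matrix.data.groupby(labels).groups.items():
        group = CommunityMatrix(
            matrix.data.loc[idx], units=matrix.units, transform=matrix.transform
        )
        if mode == "si_of_means":
            profile = group.data.mean(axis=0)
            res = _result(level, profile[taxa].to_numpy(), vals, profile.sum(), table)
            si = res.si
        else:
            per_sample = sample_saprobity(group, registry, table)
            si = float(np.mean([r.si for r in per_sample]))
            lvl, deg, qc = classify_saprobic(si, table)
            profile = group.data.mean(axis=0)
            res = _result(level, profile[taxa].to_numpy(), vals, profile.sum(), table)
            res = SaprobicResult(
                sample_id=str(level),
                si=si,
                n_classified_taxa=res.n_classified_taxa,
                classified_fraction_of_abundance=res.classified_fraction_of_abundance,
                level=lvl,
                degree=deg,
                quality_class=qc,
            )
        rows.append(
            {
                group_by: level,
                "si": si,
                "level": res.level,
                "degree": res.degree,
                "quality_class": res.quality_class,
                "n_classified_taxa": res.n_classified_taxa,
                "classified_fraction_of_abundance": res.classified_fraction_of_abundance,
            }
        )
    return pd.DataFrame(rows).set_index(group_by)
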