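"""Geometric biovolume, dry weight, and biomass concentration.

Each taxon is assigned the closest standard geometric solid and a fixed
(length, width) pair in um; ``l`` and ``w`` are full dimensions
(diameters, not semi-axes). Volumes in um^3:

    sphere     (pi/6)  l^3
    oval       (pi/6)  l w^2   (prolate spheroid)
    ellipsoid  (pi/12) l w^2
    cone       (pi/12) l w^2
    cylinder   (pi/4)  l w^2

Note the ellipsoid and cone coefficients coincide: the ellipsoid class
is defined with a flattened half-width third axis (1/6 pi l w (w/2)),
which reduces to the cone formula. Both tokens are kept distinct.

Biovolume is converted to dry weight at 0.524 pg per um^3 (a standard
protist dry-weight density; overridable), and biomass concentration is
abundance (ind L^-1) times per-cell dry weight (pg), reported in
ug L^-1.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .types import CommunityMatrix, SaprolensError, TraitRegistry

__all__ = [
    "BiomassParams",
    "biovolume",
    "cell_dry_weight",
    "biomass_concentration",
    "community_biomass",
]

_LW2_COEFF = {
    "oval": math.pi / 6.0,
    "ellipsoid": math.pi / 12.0,
    "cone": math.pi / 12.0,
    "cylinder": math.pi / 4.0,
}

PG_PER_UG = 1e6


@dataclass(frozen=True)
class BiomassParams:
    """Biomass conversion parameters.

    dry_weight_density : pg per um^3 of biovolume (default 0.524).
    """

    dry_weight_density: float = 0.524

    def __post_init__(self) -> None:
        if not self.dry_weight_density > 0:
            raise SaprolensError("dry_weight_density must be positive")


def biovolume(shape: str, length_um: float, width_um: float | None = None) -> float:
    """Cell volume (um^3) for a shape class and full dimensions (um)."""
    if not length_um > 0:
        raise SaprolensError("length must be positive")
    if shape == "sphere":
        return math.pi / 6.0 * length_um**3
    try:
        coeff = _LW2_COEFF[shape]
    except KeyError:
        raise SaprolensError(f"unknown shape {shape!r}") from None
    if width_um is None:
        raise SaprolensError(f"shape {shape!r} requires a width")
    if not width_um > 0:
        raise SaprolensError("width must be positive")
    return coeff * length_um * width_um**2


def cell_dry_weight(volume_um3: float, params: BiomassParams = BiomassParams()) -> float:
    """Per-cell dry weight (pg) from biovolume (um^3)."""
    if volume_um3 < 0:
        raise SaprolensError("volume must be non-negative")
    return volume_um3 * params.dry_weight_density


def biomass_concentration(abundance_per_l: float, dry_weight_pg: float) -> float:
    """Biomass concentration (ug L^-1) from abundance and per-cell dry weight."""
    if abundance_per_l < 0 or dry_weight_pg < 0:
        raise SaprolensError("abundance and dry weight must be non-negative")
    return abundance_per_l * dry_weight_pg / PG_PER_UG


def community_biomass(
    matrix: CommunityMatrix,
    registry: TraitRegistry,
    params: BiomassParams = BiomassParams(),
) -> CommunityMatrix:
    """Element-wise biomass matrix (ug L^-1) aligned with ``matrix``.

    Every taxon with non-zero abundance anywhere must carry a shape and
    dimensions in the registry; all-zero columns pass through as zero.
    """
    if matrix.units != "ind_per_l":
        raise SaprolensError("community_biomass expects abundances in ind L^-1")
    dw = {}
    for taxon_id in matrix.taxon_ids:
        col = matrix.data[taxon_id]
        if (col == 0).all():
            dw[taxon_id] = 0.0
            continue
        rec = registry[taxon_id]
        if not rec.biomass_capable:
            raise SaprolensError(
                f"taxon {taxon_id!r} has non-zero abundance but no usable "
                "morphology (shape/length/width) in the registry"
            )
        dw[taxon_id] = cell_dry_weight(
            biovolume(rec.shape, rec.length_um, rec.width_um), params
        )
    biomass = matrix.data.mul(pd.Series(dw)) / PG_PER_UG
    return CommunityMatrix(
        biomass, sample_meta=matrix.sample_meta, units="ug_per_l",
        transform=matrix.transform,
    )
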