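"""Core domain types for protozoan community bioassessment.

The pipeline moves between four tabular objects: a trait registry
(per-taxon morphology, phylum, saprobity code, feeding guild), a
community matrix (samples x taxa abundances in individuals per litre),
an environment matrix (samples x physicochemical variables), and a
saprobic valence table (code -> numeric valence, plus the band scheme
mapping a saprobic index to a water-quality class).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHYLA",
    "SHAPES",
    "SaprolensError",
    "RegistryError",
    "MatrixError",
    "UnknownSaprobityCodeError",
    "TaxonRecord",
    "TraitRegistry",
    "CommunityMatrix",
    "EnvironmentMatrix",
    "ClassBand",
    "SaprobicValenceTable",
]

#: Heterotrophic protozoan phyla recognised by the registry.
PHYLA = frozenset(
    {"Amoebozoa", "Choanozoa", "Heliozoa", "Cercozoa", "Myzozoa", "Ciliophora"}
)

#: Geometric shape classes available for biovolume estimation.
SHAPES = frozenset({"sphere", "oval", "ellipsoid", "cone", "cylinder"})


class SaprolensError(ValueError):
    """Base class for domain validation errors."""


class RegistryError(SaprolensError):
    """Invalid or inconsistent trait-registry content."""


class MatrixError(SaprolensError):
    """Invalid community or environment matrix content."""


class UnknownSaprobityCodeError(SaprolensError):
    """A saprobity code could not be resolved to a numeric valence."""


@dataclass(frozen=True)
class TaxonRecord:
    """One taxon's traits.

    ``length_um``/``width_um`` are full cell dimensions (diameters, not
    semi-axes). ``saprobity_code`` is stored verbatim (e.g. ``"a-b"``)
    and resolved to a numeric valence only when a saprobic index is
    computed.
    """

    taxon_id: str
    name: str
    phylum: str
    shape: str | None = None
    length_um: float | None = None
    width_um: float | None = None
    saprobity_code: str | None = None
    feeding_guild: str | None = None

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise RegistryError("taxon_id must be non-empty")
        if self.phylum not in PHYLA:
            raise RegistryError(
                f"unknown phylum {self.phylum!r} for {self.taxon_id}"
            )
        if self.shape is not None and self.shape not in SHAPES:
            raise RegistryError(
                f"unknown shape {self.shape!r} for {self.taxon_id}"
            )
        for dim, value in (("length_um", self.length_um), ("width_um", self.width_um)):
            if value is not None and not value > 0:
                raise RegistryError(f"{dim} must be positive for {self.taxon_id}")
        if (
            self.length_um is not None
            and self.width_um is not None
            and self.length_um < self.width_um
        ):
            raise RegistryError(
                f"length_um < width_um for {self.taxon_id} "
                f"({self.length_um} < {self.width_um})"
            )

    @property
    def biomass_capable(self) -> bool:
        """True when the record carries enough morphology for a biovolume."""
        if self.shape is None or self.length_um is None:
            return False
        if self.shape != "sphere" and self.width_um is None:
            return False
        return True


class TraitRegistry:
    """Ordered collection of :class:`TaxonRecord`, unique by ``taxon_id``."""

    def __init__(self, records: Iterable[TaxonRecord]):
        self._records: dict[str, TaxonRecord] = {}
        for rec in records:
            if rec.taxon_id in self._records:
                raise RegistryError(f"duplicate taxon_id {rec.taxon_id!r}")
            self._records[rec.taxon_id] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self._records

    def __getitem__(self, taxon_id: str) -> TaxonRecord:
        try:
            return self._records[taxon_id]
        except KeyError:
            raise RegistryError(f"taxon {taxon_id!r} not in registry") from None

    def __iter__(self):
        return iter(self._records.values())

    @property
    def taxon_ids(self) -> list[str]:
        return list(self._records)

    def phylum_of(self, taxon_id: str) -> str:
        return self[taxon_id].phylum

    def to_frame(self) -> pd.DataFrame:
        """Registry as a DataFrame indexed by taxon_id."""
        rows = [
            {
                "taxon_id": r.taxon_id,
                "name": r.name,
                "phylum": r.phylum,
                "shape": r.shape,
                "length_um": r.length_um,
                "width_um": r.width_um,
                "saprobity_code": r.saprobity_code,
                "feeding_guild": r.feeding_guild,
            }
            for r in self
        ]
        return pd.DataFrame(rows).set_index("taxon_id")

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitRegistry):
            return NotImplemented
        return self._records == other._records


def _check_sample_meta(
    data: pd.DataFrame, sample_meta: pd.DataFrame | None
) -> pd.DataFrame | None:
    if sample_meta is None:
        return None
    meta = sample_meta.reindex(data.index)
    if "site" in meta.columns and "month" in meta.columns:
        pairs = meta[["site", "month"]].dropna()
        if pairs.duplicated().any():
            raise MatrixError("duplicate (site, month) pairs in sample metadata")
    return meta


@dataclass
class CommunityMatrix:
    """Samples x taxa abundance table.

    ``data`` is indexed by sample_id with taxon_id columns; absence is 0,
    never missing. ``units`` is ``"ind_per_l"`` for concentrations,
    ``"raw"`` for untransformed counts, ``"ug_per_l"`` for biomass.
    ``transform`` records any value transform already applied (guards
    against double square-root transforming).
    """

    data: pd.DataFrame
    sample_meta: pd.DataFrame | None = None
    units: str = "ind_per_l"
    transform: str = "none"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise MatrixError("duplicate sample_id")
        if self.data.columns.has_duplicates:
            raise MatrixError("duplicate taxon_id column")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise MatrixError("missing values: absence must be coded as 0")
        if (values < 0).any():
            raise MatrixError("negative abundance")
        self.data = self.data.astype(float)
        self.sample_meta = _check_sample_meta(self.data, self.sample_meta)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def totals(self) -> pd.Series:
        """Per-sample total abundance."""
        return self.data.sum(axis=1)

    def factor(self, name: str) -> pd.Series:
        """Sample metadata factor (e.g. ``site``, ``season``)."""
        if self.sample_meta is None or name not in self.sample_meta.columns:
            raise MatrixError(f"no {name!r} labels on samples")
        return self.sample_meta[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CommunityMatrix):
            return NotImplemented
        return (
            self.data.equals(other.data)
            and self.units == other.units
            and self.transform == other.transform
        )


@dataclass
class EnvironmentMatrix:
    """Samples x environmental variables, with a unit string per variable."""

    data: pd.DataFrame
    units: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise MatrixError("duplicate sample_id")
        if self.data.columns.has_duplicates:
            raise MatrixError("duplicate variable")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise MatrixError("missing environmental values")
        self.data = self.data.astype(float)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def constant_variables(self) -> list[str]:
        """Variables with zero variance (undefined under standardisation)."""
        std = self.data.std(ddof=0)
        return list(std.index[std == 0.0])

    def align_with(self, community: CommunityMatrix) -> "EnvironmentMatrix":
        """Restrict and reorder samples to match a community matrix."""
        missing = set(community.sample_ids) - set(self.data.index)
        if missing:
            raise MatrixError(f"environment matrix lacks samples: {sorted(missing)}")
        return EnvironmentMatrix(self.data.loc[community.sample_ids], dict(self.units))


@dataclass(frozen=True)
class ClassBand:
    """One saprobic band: ``[lower, upper)`` -> level / degree / class."""

    lower: float
    upper: float
    level: str
    degree: str
    quality_class: str


class SaprobicValenceTable:
    """Saprobity code valences plus the band scheme for classification.

    Bands must be contiguous, half-open ``[lower, upper)`` intervals
    covering ``[1.0, 4.0)``; valences must lie in ``[1, 4]``.
    """

    def __init__(self, code_to_s: Mapping[str, float], bands: Sequence[ClassBand]):
        self.code_to_s = dict(code_to_s)
        for code, s in self.code_to_s.items():
            if not (1.0 <= s <= 4.0):
                raise SaprolensError(f"valence {s} for code {code!r} outside [1, 4]")
        bands = sorted(bands, key=lambda b: b.lower)
        if not bands:
            raise SaprolensError("no class bands")
        if bands[0].lower != 1.0 or bands[-1].upper != 4.0:
            raise SaprolensError("class bands must cover [1.0, 4.0)")
        for a, b in zip(bands, bands[1:]):
            if a.upper != b.lower:
                raise SaprolensError(
                    f"class bands not contiguous at {a.upper} / {b.lower}"
                )
        self.bands = list(bands)

    def resolve(self, code: str) -> float:
        """Numeric valence S for a saprobity code; unknown codes raise."""
        if not code:
            raise UnknownSaprobityCodeError("empty saprobity code")
        try:
            return self.code_to_s[code]
        except KeyError:
            raise UnknownSaprobityCodeError(
                f"saprobity code {code!r} has no valence in the table"
            ) from None

    def classify(self, si: float) -> ClassBand:
        """Band containing ``si`` (lower-inclusive, upper-exclusive)."""
        for band in self.bands:
            if band.lower <= si < band.upper:
                return band
        raise SaprolensError(f"saprobic index {si} outside [1.0, 4.0)")
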