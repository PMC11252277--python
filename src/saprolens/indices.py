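"""Community structure indices.

Richness S is the count of taxa present; Shannon diversity
H' = -sum p_i ln p_i over present taxa (natural-log units); dominance
follows the frequency-weighted convention of Xu & Chen,
(n_i / N) * f_i, where n_i is a taxon's total abundance over the sample
collection, N the grand total, and f_i the fraction of samples in which
the taxon occurs. Taxa at or above the 0.02 dominance threshold are
flagged dominant.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CommunityMatrix, MatrixError, SaprolensError, TraitRegistry

__all__ = [
    "richness",
    "shannon",
    "occurrence_frequency",
    "dominance",
    "group_shares",
    "summarize_by_factor",
    "sample_indices",
    "DOMINANCE_THRESHOLD",
]

DOMINANCE_THRESHOLD = 0.02


def _as_vector(abundances) -> np.ndarray:
    vec = np.asarray(abundances, dtype=float)
    if vec.ndim != 1:
        raise SaprolensError("expected a 1-d abundance vector")
    if (vec < 0).any():
        raise SaprolensError("negative abundance")
    return vec


def richness(abundances) -> int:
    """Number of taxa with strictly positive abundance."""
    return int((_as_vector(abundances) > 0).sum())


def shannon(abundances) -> float:
    """Shannon diversity H' = -sum p ln p (nats) over positive entries."""
    vec = _as_vector(abundances)
    total = vec.sum()
    if total == 0:
        raise SaprolensError("Shannon index undefined for an all-zero vector")
    p = vec[vec > 0] / total
    p = p[p > 0]  # guard against underflow of extreme abundance ratios
    return float(-(p * np.log(p)).sum())


def occurrence_frequency(matrix: CommunityMatrix, taxon_id: str) -> float:
    """Fraction of samples in which ``taxon_id`` is present."""
    if taxon_id not in matrix.data.columns:
        raise MatrixError(f"taxon {taxon_id!r} not in matrix")
    col = matrix.data[taxon_id]
    return float((col > 0).mean())


def dominance(
    matrix: CommunityMatrix, threshold: float = DOMINANCE_THRESHOLD
) -> pd.DataFrame:
    """Frequency-weighted dominance per taxon over a sample collection.

    Returns a DataFrame indexed by taxon_id with columns
    ``relative_abundance``, ``occurrence_frequency``, ``dominance`` and
    ``is_dominant`` (inclusive at the threshold), sorted by dominance
    descending.
    """
    if matrix.data.empty:
        raise MatrixError("empty community matrix")
    totals = matrix.data.sum(axis=0)
    grand = totals.sum()
    if grand == 0:
        raise MatrixError("all-zero community matrix")
    rel = totals / grand
    freq = (matrix.data > 0).mean(axis=0)
    dom = rel * freq
    out = pd.DataFrame(
        {
            "relative_abundance": rel,
            "occurrence_frequency": freq,
            "dominance": dom,
            "is_dominant": dom >= threshold,
        }
    )
    out.index.name = "taxon_id"
    return out.sort_values("dominance", ascending=False)


def group_shares(
    matrix: CommunityMatrix, registry: TraitRegistry, by: str = "phylum"
) -> pd.DataFrame:
    """Per-group totals and percentage shares (groups default to phyla).

    Works on abundance or biomass matrices alike; percentages are
    100 * group total / grand total and sum to 100 within rounding.
    """
    if by != "phylum":
        raise SaprolensError(f"unsupported grouping {by!r}")
    groups = {}
    for taxon_id in matrix.taxon_ids:
        groups[taxon_id] = registry[taxon_id].phylum
    totals = matrix.data.sum(axis=0).groupby(pd.Series(groups)).sum()
    grand = totals.sum()
    if grand == 0:
        raise MatrixError("all-zero matrix")
    out = pd.DataFrame(
        {"total": totals, "mean_per_sample": totals / len(matrix.sample_ids),
         "percent": 100.0 * totals / grand}
    ).sort_values("total", ascending=False)
    out.index.name = by
    return out


def sample_indices(matrix: CommunityMatrix) -> pd.DataFrame:
    """Per-sample richness, Shannon H' and total abundance."""
    rows = {}
    for sid, row in matrix.data.iterrows():
        vec = row.to_numpy()
        rows[sid] = {
            "richness": richness(vec),
            "shannon": shannon(vec) if vec.sum() > 0 else np.nan,
            "total": float(vec.sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def summarize_by_factor(matrix: CommunityMatrix, factor: str) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of per-sample indices per factor level.

    ``factor`` is a sample-metadata column (``site`` or ``season``).
    Also reports pooled richness and Shannon of the level's mean
    abundance profile, matching how campaign-level community figures
    are usually quoted.
    """
    labels = matrix.factor(factor)
    per_sample = sample_indices(matrix)
    out = []
    for level, idx in per_sample.groupby(labels).groups.items():
        sub = per_sample.loc[idx]
        profile = matrix.data.loc[idx].mean(axis=0)
        out.append(
            {
                factor: level,
                "n_samples": len(idx),
                "abundance_mean": sub["total"].mean(),
                "abundance_sd": sub["total"].std(ddof=1),
                "richness_mean": sub["richness"].mean(),
                "shannon_mean": sub["shannon"].mean(),
                "pooled_richness": richness(profile),
                "pooled_shannon": shannon(profile) if profile.sum() > 0 else np.nan,
            }
        )
    return pd.DataFrame(out).set_index(factor)
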