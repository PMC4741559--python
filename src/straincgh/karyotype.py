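"""Electrophoretic-karyotype relatedness.

A digitized gel lane is a list of band sizes (kb) per strain.  Bands from all
strains are pooled and greedily binned by relative size tolerance, strains are
scored for presence/absence per bin, pairwise similarity is the Jaccard
coefficient on bin sets, and the strain tree is UPGMA on 1 - Jaccard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree import Dendrogram, agglomerate

__all__ = [
    "BandPattern",
    "bin_bands",
    "jaccard_similarity",
    "similarity_to_distance",
    "upgma",
]


@dataclass(frozen=True)
class BandPattern:
    """One strain's electrophoretic fingerprint: band sizes in kb.

    The list may contain near-duplicate sizes; co-migrating chromosomes are
    collapsed later by binning, so a strain counts at most once per bin.
    """

    strain_id: str
    band_sizes_kb: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.band_sizes_kb:
            raise ValueError(f"strain {self.strain_id!r} has no bands")
        if any(s <= 0 for s in self.band_sizes_kb):
            raise ValueError(f"strain {self.strain_id!r} has a non-positive band size")


def bin_bands(patterns: list[BandPattern], tolerance: float = 0.05) -> pd.DataFrame:
    """Pool all band sizes, sort them, and greedily merge into bins.

    A size joins the current bin only if afterwards every two sizes in the
    bin differ by at most ``tolerance * mean(bin)``; since sizes are sorted
    this reduces to checking the bin's max - min against its mean.  Returns a
    presence/absence matrix (strains x bins, values 0/1) whose columns are
    the bin mean sizes.
    """
    if not patterns:
        raise ValueError("empty pattern list")
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    ids = [p.strain_id for p in patterns]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids in band patterns")

    pooled = sorted(
        (size, p.strain_id) for p in patterns for size in p.band_sizes_kb
    )
    bins: list[list[tuple[float, str]]] = []
    current: list[tuple[float, str]] = []
    for size, strain in pooled:
        if not current:
            current = [(size, strain)]
            continue
        lo = current[0][0]
        members = [s for s, _ in current] + [size]
        if size - lo <= tolerance * (sum(members) / len(members)):
            current.append((size, strain))
        else:
            bins.append(current)
            current = [(size, strain)]
    if current:
        bins.append(current)

    means = [sum(s for s, _ in b) / len(b) for b in bins]
    presence = pd.DataFrame(
        0, index=pd.Index(ids, name="strain_id"), columns=means, dtype=int
    )
    for b, mean in zip(bins, means):
        for _, strain in b:
            presence.loc[strain, mean] = 1
    return presence


def jaccard_similarity(presence: pd.DataFrame) -> pd.DataFrame:
    """Jaccard coefficient between strain bin sets: |shared| / |union|."""
    mat = presence.to_numpy()
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    counts = mat.sum(axis=1)
    if (counts == 0).any():
        empty = presence.index[counts == 0].tolist()
        raise ValueError(f"strains with zero bins have undefined Jaccard: {empty}")
    inter = mat @ mat.T
    union = counts[:, None] + counts[None, :] - inter
    sim = inter / union
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=presence.index, columns=presence.index)


def similarity_to_distance(similarity: pd.DataFrame) -> pd.DataFrame:
    """Standard complement distance 1 - J with an exactly zero diagonal."""
    d = 1.0 - similarity.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return pd.DataFrame(d, index=similarity.index, columns=similarity.columns)


def upgma(distances: pd.DataFrame) -> Dendrogram:
    """UPGMA tree: size-weighted average linkage, merge height = d / 2,
    ties broken by lexicographic smallest-leaf-label order."""
    return agglomerate(
        distances.to_numpy(dtype=float), list(distances.index), method="average"
    )
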