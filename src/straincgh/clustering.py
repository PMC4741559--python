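"""Strain relatedness from array-CGH profiles: complete-linkage hierarchical
clustering on Euclidean distances between strain columns."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tree import Dendrogram, agglomerate

__all__ = ["euclidean_distances", "complete_linkage"]

log = logging.getLogger(__name__)


def euclidean_distances(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distance between strain columns.

    Genes with a missing value in either strain of a pair are excluded for
    that pair (pairwise-complete); a pair sharing fewer than two observed
    genes is rejected.  d(a, b) = sqrt(sum_g (x[g,a] - x[g,b])^2).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two strains")
    X = matrix.to_numpy(dtype=float)
    strains = list(matrix.columns)
    n = len(strains)
    d = np.zeros((n, n))
    if not np.isnan(X).any():
        diff = X[:, :, None] - X[:, None, :]
        d = np.sqrt(np.einsum("gij,gij->ij", diff, diff))
    else:
        observed = ~np.isnan(X)
        min_shared = X.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                mask = observed[:, i] & observed[:, j]
                shared = int(mask.sum())
                min_shared = min(min_shared, shared)
                if shared < 2:
                    raise ValueError(
                        f"strains {strains[i]!r} and {strains[j]!r} share only "
                        f"{shared} observed gene(s)"
                    )
                diff = X[mask, i] - X[mask, j]
                d[i, j] = d[j, i] = float(np.sqrt(np.dot(diff, diff)))
        log.info("pairwise-complete distances: minimum shared genes = %d", min_shared)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=strains, columns=strains)


def complete_linkage(distances: pd.DataFrame) -> Dendrogram:
    """Complete-linkage tree: inter-cluster distance is the maximum
    cross-pair distance, merge height equals that distance, ties broken by
    lexicographic smallest-leaf-label order."""
    return agglomerate(
        distances.to_numpy(dtype=float), list(distances.index), method="complete"
    )
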