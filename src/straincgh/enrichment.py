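"""Functional-category overrepresentation.

Exact hypergeometric upper-tail test per term with Benjamini-Hochberg FDR
across all tested terms, significance at q < alpha (default 0.05).  Terms are
flat gene sets (GMT style); no ontology-graph propagation is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "Term",
    "TermCollection",
    "hypergeom_upper_tail",
    "bh_fdr",
    "enrich",
]


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"term {self.term_id!r} has no members")


class TermCollection:
    """Ordered collection of named gene sets with unique ids."""

    def __init__(self, terms: list[Term] | tuple[Term, ...] = ()):
        ids = [t.term_id for t in terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate term ids")
        self._terms: list[Term] = list(terms)

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self):
        return iter(self._terms)

    def __getitem__(self, term_id: str) -> Term:
        for t in self._terms:
            if t.term_id == term_id:
                return t
        raise KeyError(term_id)

    def gene_space(self) -> frozenset[str]:
        """Union of all member sets — the annotated gene space."""
        out: set[str] = set()
        for t in self._terms:
            out |= t.members
        return frozenset(out)


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Summed in log space over the upper tail for numerical stability; exact
    (to ~1e-15) against direct enumeration.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if K > N or n > N:
        raise ValueError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    lo = max(0, n - (N - K))  # smallest achievable count
    if k <= lo:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    p = float(min(np.exp(logsumexp(logp)), 1.0))
    return max(p, 1e-300)  # keep p strictly positive under extreme underflow


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j on the sorted p-values, clipped
    at 1 and mapped back to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enrich(
    selected,
    terms: TermCollection,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Overrepresentation of ``selected`` genes in each term against
    ``universe``.

    Selected genes outside the universe are dropped with a warning; term
    membership is intersected with the universe and every term retaining at
    least one member is tested (k = 0 included, giving p = 1).  q-values come
    from BH across all tested terms jointly; ``significant`` means q < alpha.
    Rows are sorted by (q, p, term_id).
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    selected = frozenset(selected)
    outside = selected - universe
    if outside:
        warnings.warn(
            f"dropping {len(outside)} selected gene(s) outside the universe",
            stacklevel=2,
        )
        selected &= universe
    if not selected:
        warnings.warn("no selected genes inside the universe; all p = 1", stacklevel=2)

    N = len(universe)
    n = len(selected)
    rows = []
    for term in terms:
        members = term.members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & selected)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append((term.term_id, term.name, k, K, n, N, p))
    result = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "K", "n", "N", "p_value"]
    )
    if result.empty:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["q_value"] = bh_fdr(result["p_value"].to_numpy())
    result["significant"] = result["q_value"] < alpha
    return result.sort_values(
        ["q_value", "p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
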