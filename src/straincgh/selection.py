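"""Divergent-gene selection.

A gene is selected when its re-normalized log2 ratio in at least one strain
exceeds k (default 4) global standard deviations in absolute value, where the
global SD is the population SD pooled over every observed gene x strain
value.  Both tails are eligible: gains and losses are equally divergent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgh import genome_sorted

__all__ = ["SelectionResult", "select_divergent", "selection_heatmap_table"]


@dataclass(frozen=True)
class SelectionResult:
    k: float
    global_sd: float
    threshold: float          # k * global_sd
    max_abs: pd.Series        # per-gene max |log2| over strains
    selected: frozenset[str]  # genes with max_abs strictly above threshold

    def summary(self) -> dict:
        return {
            "k": self.k,
            "global_sd": self.global_sd,
            "threshold": self.threshold,
            "n_genes": int(len(self.max_abs)),
            "n_selected": int(len(self.selected)),
        }

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.max_abs.index,
                "max_abs_log2": self.max_abs.to_numpy(),
                "selected": [
                    int(g in self.selected) for g in self.max_abs.index
                ],
            }
        )


def select_divergent(matrix: pd.DataFrame, k: float = 4.0) -> SelectionResult:
    """Select genes whose |value| strictly exceeds ``k`` pooled SDs in at
    least one strain.  Missing values are excluded from both the pooled SD
    and the per-gene maxima."""
    if not k > 0:
        raise ValueError("k must be positive")
    values = matrix.to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    if observed.size == 0:
        raise ValueError("matrix has no observed values")
    global_sd = float(np.std(observed, ddof=0))
    threshold = k * global_sd
    with np.errstate(invalid="ignore"):
        max_abs = np.nanmax(
            np.where(np.isnan(values), -np.inf, np.abs(values)), axis=1
        )
    max_abs = pd.Series(max_abs, index=matrix.index, name="max_abs_log2")
    selected = frozenset(matrix.index[max_abs.to_numpy() > threshold])
    return SelectionResult(
        k=float(k),
        global_sd=global_sd,
        threshold=float(threshold),
        max_abs=max_abs,
        selected=selected,
    )


def selection_heatmap_table(
    matrix: pd.DataFrame,
    selection: SelectionResult,
    annotation: pd.DataFrame,
    category_assignment: dict[str, str],
    strain_order: list[str] | None = None,
) -> pd.DataFrame:
    """Rendering table for the selected-gene heatmap.

    Rows are the selected genes grouped by assigned category and, within a
    category, by genome position; columns are the strains in cluster (or
    given) order; cells are the re-normalized log2 ratios.  Genes without a
    category fall into ``unassigned``; selected genes absent from the
    annotation are kept, flagged ``unplaced`` and placed after the located
    genes of their category.
    """
    if strain_order is None:
        strain_order = list(matrix.columns)
    if set(strain_order) != set(matrix.columns):
        raise ValueError("strain_order must be a permutation of the matrix columns")

    ann = genome_sorted(annotation).set_index("gene_id")
    rows = []
    for gene in sorted(selection.selected):
        category = category_assignment.get(gene, "unassigned")
        if gene in ann.index:
            chrom = int(ann.at[gene, "chromosome"])
            start = int(ann.at[gene, "start"])
            unplaced = 0
        else:
            chrom, start, unplaced = np.inf, np.inf, 1
        rows.append((category, chrom, start, gene, unplaced))
    rows.sort(key=lambda r: (r[0], r[1], r[2], r[3]))

    header = ["gene_id", "category", "chromosome", "start", "unplaced"]
    out = pd.DataFrame(
        [
            {
                "gene_id": gene,
                "category": category,
                "chromosome": -1 if unplaced else int(chrom),
                "start": -1 if unplaced else int(start),
                "unplaced": unplaced,
                **{s: matrix.at[gene, s] for s in strain_order},
            }
            for category, chrom, start, gene, unplaced in rows
        ],
        columns=header + list(strain_order),
    )
    return out
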