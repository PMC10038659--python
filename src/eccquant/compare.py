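"""Cross-comparison set algebra and display matrices.

Given per-comparison lists of significantly up- and down-regulated
proteins, this module computes exhaustive Venn partitions, the changes
shared across all comparisons in a chosen direction, and the matrices
behind the usual displays: volcano coordinates (log2 fold change vs
-log10 p) and a per-protein z-scored heatmap ordered by average-linkage
hierarchical clustering on correlation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import AbstractSet, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .tmt import ChannelDesign


@dataclass(frozen=True)
class ComparisonSet:
    """Significantly changed proteins of one comparison, split by direction."""

    label: str
    up: frozenset[str] = field(default_factory=frozenset)
    down: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        if self.up & self.down:
            raise ValueError("a protein cannot be both up- and down-regulated")


def comparison_set_from_results(label: str, results: pd.DataFrame) -> ComparisonSet:
    """Build a ComparisonSet from a differential-results table with a
    ``significant`` flag."""
    sig = results[results["significant"]]
    return ComparisonSet(
        label=label,
        up=frozenset(sig.index[sig["ratio"] > 1]),
        down=frozenset(sig.index[sig["ratio"] < 1]),
    )


def venn_partition(
    sets: Sequence[AbstractSet[str]],
    labels: Sequence[str] | None = None,
) -> dict[str, set[str]]:
    """Exhaustive disjoint partition of 2-3 sets into Venn regions.

    Region keys join the labels of included sets with ``&`` (e.g. ``"A"``
    for elements exclusive to A, ``"A&B&C"`` for the triple intersection).
    Region sets are disjoint and their union equals the union of the inputs.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_partition supports 2 or 3 sets")
    if labels is None:
        labels = [chr(ord("A") + i) for i in range(len(sets))]
    if len(labels) != len(sets):
        raise ValueError("one label per set required")
    sets = [set(s) for s in sets]
    regions: dict[str, set[str]] = {}
    n = len(sets)
    for mask in range(1, 2**n):
        included = [i for i in range(n) if mask >> i & 1]
        excluded = [i for i in range(n) if not mask >> i & 1]
        region = set.intersection(*(sets[i] for i in included))
        for i in excluded:
            region -= sets[i]
        regions["&".join(labels[i] for i in included)] = region
    return regions


def shared_direction(
    comparison_sets: Sequence[ComparisonSet], direction: str
) -> set[str]:
    """Proteins changed in the same direction in every comparison."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(comparison_sets) < 2:
        raise ValueError("need at least two comparison sets")
    members = [set(getattr(cs, direction)) for cs in comparison_sets]
    return set.intersection(*members)


@dataclass(frozen=True)
class DisplayMatrices:
    """Volcano coordinates for every tested protein plus a z-scored,
    cluster-ordered heatmap restricted to significant proteins."""

    volcano: pd.DataFrame
    heatmap: pd.DataFrame
    row_order: tuple[str, ...]


def build_display_matrices(
    results: pd.DataFrame,
    quants: pd.DataFrame,
    design: ChannelDesign,
    max_neg_log10_p: float = 300.0,
) -> DisplayMatrices:
    """Compute volcano coordinates and the clustered heatmap matrix.

    Volcano: x = log2 fold change, y = -log10 p (capped at
    ``max_neg_log10_p`` with a ``capped`` flag for p = 0). Heatmap: per-
    protein z-scored log2 channel intensities of the significant proteins,
    rows ordered by average-linkage clustering on 1 - Pearson correlation.
    """
    with np.errstate(divide="ignore"):
        neg_log_p = -np.log10(results["p_value"].to_numpy(dtype=float))
    capped = ~np.isfinite(neg_log_p) | (neg_log_p > max_neg_log10_p)
    volcano = pd.DataFrame(
        {
            "log2fc": results["log2fc"],
            "neg_log10_p": np.minimum(neg_log_p, max_neg_log10_p),
            "capped": capped,
        },
        index=results.index,
    )

    if "significant" in results.columns:
        rows = results.index[results["significant"]]
    else:
        rows = results.index
    cols = list(design.channels)
    X = np.log2(quants.loc[rows, cols].to_numpy(dtype=float))
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = (X - mean) / np.where(sd > 0, sd, 1.0)
    heatmap = pd.DataFrame(Z, index=rows, columns=cols)

    if len(rows) >= 3:
        dist = pdist(Z, metric="correlation")
        order = leaves_list(linkage(dist, method="average"))
    else:
        order = np.arange(len(rows))
    heatmap = heatmap.iloc[order]
    return DisplayMatrices(
        volcano=volcano,
        heatmap=heatmap,
        row_order=tuple(heatmap.index),
    )
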