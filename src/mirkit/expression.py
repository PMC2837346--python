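"""Expression matrices, Pearson-distance hierarchical clustering, top-N reports.

Expression of a miRNA in a library is its relative proportion: read count
divided by the library's total read count. Libraries are clustered
agglomeratively (average linkage / UPGMA) on the Pearson correlation
distance d = 1 - r between their proportion profiles, producing a sample
dendrogram ("condition tree") exportable as Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


def build_matrix(
    counts: dict[str, dict[str, int]],
    library_totals: dict[str, int],
) -> pd.DataFrame:
    """miRNA x library matrix of relative proportions.

    ``counts`` maps library -> {row_id: count}; values are count / total
    reads of that library. Rows that are zero everywhere are dropped; rows
    are sorted by id, columns follow the order of ``library_totals``.
    Libraries with zero total reads are excluded with a warning.
    """
    libs = []
    for lib, total in library_totals.items():
        if total <= 0:
            warnings.warn(f"library {lib} has zero total reads; excluded")
            continue
        libs.append(lib)
    rows = sorted({r for lib in libs for r in counts.get(lib, {})})
    mat = pd.DataFrame(0.0, index=rows, columns=libs)
    for lib in libs:
        for row, c in counts.get(lib, {}).items():
            mat.loc[row, lib] = c / library_totals[lib]
    mat = mat.loc[(mat != 0).any(axis=1)]
    return mat


def pearson_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation distance d = 1 - r, in [0, 2].

    Zero-variance vectors have undefined correlation; the distance is set
    to 1 (uninformative) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("zero-variance vector; Pearson distance set to 1")
        return 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


@dataclass
class DendrogramNode:
    """A node of the library dendrogram; leaves carry the library id."""

    height: float = 0.0
    label: Optional[str] = None
    children: list["DendrogramNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return [leaf for c in self.children for leaf in c.leaves()]

    def to_newick(self) -> str:
        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(c._newick_inner(self.height) for c in self.children)
        return f"({inner});"

    def _newick_inner(self, parent_height: float) -> str:
        length = abs(parent_height - self.height)
        if self.is_leaf:
            return f"{self.label}:{length:.10g}"
        inner = ",".join(c._newick_inner(self.height) for c in self.children)
        return f"({inner}):{length:.10g}"

    def merge_heights(self) -> list[float]:
        if self.is_leaf:
            return []
        out = [self.height]
        for c in self.children:
            out.extend(c.merge_heights())
        return sorted(out)


def hierarchical_cluster(matrix: pd.DataFrame) -> DendrogramNode:
    """Average-linkage agglomeration of libraries on Pearson distance.

    Ties are broken deterministically: among pairs at the minimal distance
    the pair whose (sorted) leaf-label keys are lexicographically smallest
    merges first. Average linkage = unweighted mean of the original
    pairwise distances between the members of the two clusters (UPGMA),
    which guarantees non-decreasing merge heights.
    """
    libs = list(matrix.columns)
    if len(libs) < 2:
        raise ValueError("at least 2 libraries required for clustering")
    base = {
        (a, b): pearson_distance(matrix[a].to_numpy(), matrix[b].to_numpy())
        for i, a in enumerate(libs)
        for b in libs[i + 1 :]
    }

    def dist(mem_a: tuple[str, ...], mem_b: tuple[str, ...]) -> float:
        total = 0.0
        for a in mem_a:
            for b in mem_b:
                total += base[(a, b)] if (a, b) in base else base[(b, a)]
        return total / (len(mem_a) * len(mem_b))

    clusters: dict[tuple[str, ...], DendrogramNode] = {
        (lib,): DendrogramNode(height=0.0, label=lib) for lib in libs
    }
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, ka in enumerate(keys):
            for kb in keys[i + 1 :]:
                d = dist(ka, kb)
                cand = (d, ka, kb)
                if best is None or cand < best:
                    best = cand
        d, ka, kb = best
        node = DendrogramNode(
            height=d, children=[clusters.pop(ka), clusters.pop(kb)]
        )
        clusters[tuple(sorted(ka + kb))] = node
    return next(iter(clusters.values()))


def top_n_report(
    matrix: pd.DataFrame, n: int = 10
) -> tuple[dict[str, list[str]], list[str]]:
    """Per-library top-``n`` rows by proportion, plus the non-redundant union.

    Within a library, rows with zero proportion are not ranked; ties are
    broken by row id. Returns ({library: ranked ids}, sorted union list).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked: dict[str, list[str]] = {}
    for lib in matrix.columns:
        col = matrix[lib]
        nonzero = col[col > 0]
        order = sorted(nonzero.index, key=lambda r: (-nonzero[r], r))
        ranked[lib] = order[:n]
    union = sorted({r for ids in ranked.values() for r in ids})
    return ranked, union


def rank_table_to_matrix(ranks: pd.DataFrame) -> pd.DataFrame:
    """Convert a printed rank table (row = miRNA, column = library, value =
    rank or blank) into a proportion-like matrix whose top-N ordering
    reproduces the ranks (value 1/rank, 0 where absent)."""
    mat = pd.DataFrame(0.0, index=ranks.index, columns=ranks.columns)
    for lib in ranks.columns:
        col = pd.to_numeric(ranks[lib], errors="coerce")
        for row, val in col.items():
            if pd.notna(val) and val > 0:
                mat.loc[row, lib] = 1.0 / float(val)
    return mat
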