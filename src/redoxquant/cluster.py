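"""Hierarchical clustering of log2 fold-change profiles and tree export.

Profiles are short time-course vectors (log2 treated/control at 5/30/120
min), so shape similarity matters more than magnitude: the default distance
is 1 minus the *uncentered* correlation (the default similarity of the
classic Cluster 3.0 tool), with centered Pearson and Euclidean available.
Agglomeration is implemented directly (average/complete/single linkage via
Lance-Williams updates) with a fully specified tie-break — the candidate
pair with the smallest indices merges first — so trees are deterministic
and row-order reproducible.

Trees can be exported as Newick and as Cluster-3.0-compatible CDT + GTR
files for heatmap viewers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd

TIMEPOINTS = (5, 30, 120)

DISTANCES = ("uncentered", "pearson", "euclidean")
LINKAGES = ("average", "complete", "single")


class ClusteringError(ValueError):
    pass


def log2_profile_matrix(source) -> pd.DataFrame:
    """Entity x timepoint matrix of log2 linear fold changes.

    *source* may be a DataFrame in the packaged reference-table layout
    (columns ``peptide``, ``accession``, ``iodo_fc_5/30/120``) or a sequence
    of redox calls (their per-timepoint mean iodoTMT fold changes are used).
    Entities with a missing fold change at any timepoint are dropped with a
    warning; non-positive fold changes are an error.
    """
    if isinstance(source, pd.DataFrame):
        fc = source[[f"iodo_fc_{tp}" for tp in TIMEPOINTS]].astype(float)
        ids = _unique_ids(
            [f"{p}|{a}" for p, a in zip(source["peptide"], source["accession"])]
        )
        fc.index = ids
    else:
        rows = {}
        for call in source:
            rows[f"{call.peptide}|{call.accession}"] = [
                call.iodo_results[tp].mean_fc if tp in call.iodo_results else np.nan
                for tp in TIMEPOINTS
            ]
        fc = pd.DataFrame.from_dict(rows, orient="index")
        if fc.empty:
            fc = pd.DataFrame(columns=list(range(len(TIMEPOINTS))))
        fc.index = _unique_ids(list(fc.index))
    fc.columns = list(TIMEPOINTS)

    incomplete = fc.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropping {int(incomplete.sum())} entities with missing fold changes"
        )
        fc = fc[~incomplete]
    nonpositive = (fc <= 0).any(axis=1)
    if nonpositive.any():
        raise ClusteringError(
            f"non-positive fold change for {list(fc.index[nonpositive])[:3]}"
        )
    return np.log2(fc)


def _unique_ids(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in ids:
        seen[name] = seen.get(name, 0) + 1
        out.append(name if seen[name] == 1 else f"{name}#{seen[name]}")
    return out


@dataclass
class ClusterTree:
    """Full agglomeration history over n leaves.

    ``merges`` has n-1 rows ``(left, right, height, size)`` where ``left`` and
    ``right`` are node ids (leaves are 0..n-1; merge i creates node n+i), in
    non-decreasing height order.
    """

    merges: np.ndarray
    leaf_ids: tuple[str, ...]
    distance: str
    linkage: str
    flags: tuple[str, ...] = ()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the dendrogram."""
        n = self.n_leaves

        def walk(node: int) -> list[int]:
            if node < n:
                return [node]
            left, right = int(self.merges[node - n][0]), int(self.merges[node - n][1])
            return walk(left) + walk(right)

        return [self.leaf_ids[i] for i in walk(2 * n - 2)]

    def to_newick(self) -> str:
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        for step, (left, right, height, _) in enumerate(self.merges):
            heights[n + step] = float(height)

        def render(node: int) -> str:
            if node < n:
                name = self.leaf_ids[node].replace("(", "_").replace(")", "_")
                name = name.replace(",", "_").replace(":", "_").replace(";", "_")
                name = name.replace(" ", "_")
                return name
            left, right, height, _ = self.merges[node - n]
            parts = []
            for child in (int(left), int(right)):
                branch = max(float(height) - heights[child], 0.0)
                parts.append(f"{render(child)}:{branch:.6g}")
            return f"({parts[0]},{parts[1]})"

        return render(2 * n - 2) + ";"


def _distance_matrix(X: np.ndarray, distance: str) -> tuple[np.ndarray, list[str]]:
    flags: list[str] = []
    if distance == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(axis=2)), flags

    norms = np.linalg.norm(X, axis=1)
    zero_norm = norms == 0
    if distance == "pearson":
        sd = X.std(axis=1)
        degenerate = sd == 0
        if degenerate.any():
            flags.append(f"uncentered-fallback:{int(degenerate.sum())}-rows")
    else:
        degenerate = np.zeros(len(X), dtype=bool)
        if zero_norm.any():
            flags.append(f"zero-profile:{int(zero_norm.sum())}-rows")

    def corr(A: np.ndarray) -> np.ndarray:
        ns = np.linalg.norm(A, axis=1)
        ns = np.where(ns == 0, 1.0, ns)
        return (A @ A.T) / np.outer(ns, ns)

    uncentered = corr(X)
    if distance == "uncentered":
        r = uncentered
        r[zero_norm, :] = 0.0
        r[:, zero_norm] = 0.0
    else:
        centered = corr(X - X.mean(axis=1, keepdims=True))
        # zero-variance rows have no centered correlation; fall back to the
        # uncentered form for any pair involving one
        use_fallback = degenerate[:, None] | degenerate[None, :]
        r = np.where(use_fallback, uncentered, centered)
    np.fill_diagonal(r, 1.0)
    return 1.0 - r, flags


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "uncentered",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerate profile rows into a :class:`ClusterTree`.

    O(n^3) agglomeration with Lance-Williams updates; at each step the
    closest active pair merges, ties resolved in favor of the smallest node
    indices, so the tree is fully deterministic.
    """
    if distance not in DISTANCES:
        raise ClusteringError(f"unknown distance {distance!r}; use one of {DISTANCES}")
    if linkage not in LINKAGES:
        raise ClusteringError(f"unknown linkage {linkage!r}; use one of {LINKAGES}")
    n = len(matrix)
    if n < 2:
        raise ClusteringError("need at least two rows to cluster")

    X = matrix.to_numpy(dtype=float)
    D, flags = _distance_matrix(X, distance)

    size = {i: 1 for i in range(n)}
    dist: dict[int, dict[int, float]] = {
        i: {j: float(D[i, j]) for j in range(n) if j != i} for i in range(n)
    }
    active = set(range(n))
    merges = np.empty((n - 1, 4), dtype=float)
    for step in range(n - 1):
        best = None
        nodes = sorted(active)
        for ai, i in enumerate(nodes):
            for j in nodes[ai + 1 :]:
                d = dist[i][j]
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        new = n + step
        merges[step] = (i, j, d, size[i] + size[j])
        size[new] = size[i] + size[j]
        dist[new] = {}
        for k in active - {i, j}:
            dik, djk = dist[k][i], dist[k][j]
            if linkage == "average":
                dnew = (size[i] * dik + size[j] * djk) / (size[i] + size[j])
            elif linkage == "complete":
                dnew = max(dik, djk)
            else:
                dnew = min(dik, djk)
            dist[new][k] = dnew
            dist[k][new] = dnew
        active -= {i, j}
        active.add(new)
    return ClusterTree(
        merges=merges,
        leaf_ids=tuple(matrix.index),
        distance=distance,
        linkage=linkage,
        flags=tuple(flags),
    )


def cut_tree(tree: ClusterTree, k: int) -> dict[str, int]:
    """Partition leaves into k groups by removing the k-1 highest merges.

    Cluster ids are assigned 1..k ordered by descending size, ties broken by
    first appearance in leaf order.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ClusteringError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        left, right, _, _ = tree.merges[step]
        new = n + step
        parent[find(int(left))] = new
        parent[find(int(right))] = new

    roots = [find(i) for i in range(n)]
    order = tree.leaf_order()
    index_of = {name: i for i, name in enumerate(tree.leaf_ids)}
    first_seen: dict[int, int] = {}
    counts: dict[int, int] = {}
    for pos, name in enumerate(order):
        root = roots[index_of[name]]
        counts[root] = counts.get(root, 0) + 1
        first_seen.setdefault(root, pos)
    ranked = sorted(counts, key=lambda r: (-counts[r], first_seen[r]))
    relabel = {root: rank + 1 for rank, root in enumerate(ranked)}
    return {name: relabel[roots[i]] for name, i in index_of.items()}


def cluster_sizes(assignment: Mapping[str, int]) -> list[int]:
    """Cluster sizes in descending order."""
    counts: dict[int, int] = {}
    for cid in assignment.values():
        counts[cid] = counts.get(cid, 0) + 1
    return sorted(counts.values(), reverse=True)


def write_cdt_gtr(
    tree: ClusterTree,
    matrix: pd.DataFrame,
    cdt_target: Union[str, TextIO],
    gtr_target: Union[str, TextIO],
) -> None:
    """Write Cluster-3.0-compatible clustered data table (CDT) and gene tree
    (GTR) files.

    GTR rows list each merge as ``NODEiX childA childB similarity`` with
    similarity = 1 - merge height; the CDT lists rows in dendrogram leaf
    order with GENE ids matching the GTR.
    """
    if isinstance(cdt_target, str):
        with open(cdt_target, "w") as fh:
            write_cdt_gtr(tree, matrix, fh, gtr_target)
            return
    if isinstance(gtr_target, str):
        with open(gtr_target, "w") as fh:
            write_cdt_gtr(tree, matrix, cdt_target, fh)
            return

    n = tree.n_leaves
    gene_id = {name: f"GENE{index_}X" for index_, name in enumerate(tree.leaf_ids)}

    def node_name(node: int) -> str:
        if node < n:
            return gene_id[tree.leaf_ids[node]]
        return f"NODE{node - n + 1}X"

    for step, (left, right, height, _) in enumerate(tree.merges):
        gtr_target.write(
            f"NODE{step + 1}X\t{node_name(int(left))}\t{node_name(int(right))}\t"
            f"{1.0 - float(height):.6f}\n"
        )

    columns = [str(c) for c in matrix.columns]
    cdt_target.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(columns) + "\n")
    cdt_target.write("EWEIGHT\t\t\t" + "\t" + "\t".join(["1"] * len(columns)) + "\n")
    for name in tree.leaf_order():
        values = "\t".join(f"{v:.6f}" for v in matrix.loc[name])
        cdt_target.write(f"{gene_id[name]}\t{name}\t{name}\t1\t{values}\n")
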