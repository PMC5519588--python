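"""Clustering the conspecificity matrix and evaluating species partitions.

The conspecificity score is a similarity; clustering needs a distance.  We
rescale the complement of the score to [0, 1] using the off-diagonal extrema
(min-max complement), then run deterministic agglomerative clustering.
Ties in merge distance are broken by the lexicographically smallest
individual label contained in each candidate cluster, so the induced
partition is invariant to input row/column order.

Average linkage (UPGMA: merge height = mean pairwise distance between the
two clusters) is the default; complete and single linkage are available for
comparison with other heatmap-package dialects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sklearn.metrics import adjusted_rand_score

from .conspecificity import ConspecificityMatrix
from .errors import ConsistencyError, ValidationError

LINKAGES = ("average", "complete", "single")


@dataclass
class Dendrogram:
    """Merge history of agglomerative clustering over labelled leaves.

    ``merges`` lists n-1 steps as (cluster_id_a, cluster_id_b, height);
    leaves are clusters 0..n-1 and step t creates cluster n+t, scipy-style.
    Heights are non-decreasing along the sequence.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def linkage_matrix(self) -> np.ndarray:
        """SciPy-format linkage matrix (for plotting and interop)."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        rows = []
        for t, (a, b, h) in enumerate(self.merges):
            size = sizes[a] + sizes[b]
            sizes[n + t] = size
            rows.append([float(a), float(b), float(h), float(size)])
        return np.asarray(rows, dtype=float).reshape(len(rows), 4)

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + t: (a, b) for t, (a, b, _) in enumerate(self.merges)}

    def _min_label(self, cluster: int, children: dict) -> str:
        while cluster in children:
            a, b = children[cluster]
            la = self._min_label(a, children)
            lb = self._min_label(b, children)
            return min(la, lb)
        return self.labels[cluster]

    def leaf_order(self) -> list[str]:
        """Leaf order used to reorder the heatmap: left child first, where
        the left child is the one containing the lexically smallest label."""
        children = self._children()

        def walk(cluster: int) -> list[int]:
            if cluster not in children:
                return [cluster]
            a, b = children[cluster]
            if self._min_label(a, children) > self._min_label(b, children):
                a, b = b, a
            return walk(a) + walk(b)

        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0
        return [self.labels[i] for i in walk(root)]

    def leaves_of(self, cluster: int) -> set[int]:
        children = self._children()

        def walk(c: int) -> set[int]:
            if c not in children:
                return {c}
            a, b = children[c]
            return walk(a) | walk(b)

        return walk(cluster)

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        children = self._children()
        heights = {i: 0.0 for i in range(self.n_leaves)}
        for t, (_, _, h) in enumerate(self.merges):
            heights[self.n_leaves + t] = h

        def walk(cluster: int, parent_height: float) -> str:
            bl = parent_height - heights[cluster]
            if cluster not in children:
                return f"{self.labels[cluster]}:{bl:.6g}"
            a, b = children[cluster]
            if self._min_label(a, children) > self._min_label(b, children):
                a, b = b, a
            inner = ",".join(
                walk(c, heights[cluster]) for c in (a, b)
            )
            return f"({inner}):{bl:.6g}"

        if not self.merges:
            return f"{self.labels[0]};" if self.labels else ";"
        root = self.n_leaves + len(self.merges) - 1
        a, b = children[root]
        if self._min_label(a, children) > self._min_label(b, children):
            a, b = b, a
        h = heights[root]
        return f"({walk(a, h)},{walk(b, h)});"


@dataclass
class SpeciesPartition:
    """Assignment of every individual to one group label."""

    blocks: dict[str, int]

    def as_sets(self) -> set[frozenset[str]]:
        groups: dict[int, set[str]] = {}
        for ind, g in self.blocks.items():
            groups.setdefault(g, set()).add(ind)
        return {frozenset(s) for s in groups.values()}


def matrix_to_distance(matrix: ConspecificityMatrix) -> np.ndarray:
    """Min-max-rescaled complement of the conspecificity score.

    d_ij = (C_max - C_ij) / (C_max - C_min) over off-diagonal entries;
    d_ii = 0.  The diagonal (presence counts) is excluded from the extrema.
    A constant off-diagonal collapses to all-zero distances.
    """
    n = matrix.n
    if n < 2:
        raise ValidationError("need at least 2 individuals to compute distances")
    c = matrix.score.astype(float)
    off = ~np.eye(n, dtype=bool)
    cmax, cmin = c[off].max(), c[off].min()
    if cmax == cmin:
        d = np.zeros((n, n))
    else:
        d = (cmax - c) / (cmax - cmin)
    np.fill_diagonal(d, 0.0)
    return d


def _validate_distance(distance: np.ndarray) -> np.ndarray:
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValidationError("distance matrix must be symmetric")
    if np.any(d < 0):
        raise ValidationError("distance matrix must be non-negative")
    return d


def hierarchical_cluster(
    distance: np.ndarray,
    labels: list[str] | None = None,
    linkage: str = "average",
) -> Dendrogram:
    """Deterministic agglomerative clustering of a distance matrix.

    At each step the pair of active clusters at minimal distance merges;
    ties are broken by the smallest individual label contained (lexical),
    making the result invariant to input permutation up to relabelling.
    Average linkage updates follow the UPGMA (size-weighted) rule.
    """
    d = _validate_distance(distance)
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise ValidationError("labels length does not match matrix size")
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}")

    # active cluster state: id -> (size, min label); pairwise dists in dict
    active: dict[int, tuple[int, str]] = {
        i: (1, labels[i]) for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                min(active[kv[0][0]][1], active[kv[0][1]][1]),
                max(active[kv[0][0]][1], active[kv[0][1]][1]),
            ),
        )
        (a, b), h = best
        sa, la = active[a]
        sb, lb = active[b]
        merges.append((a, b, h))
        others = [k for k in active if k not in (a, b)]
        for k in others:
            da = dist[(min(a, k), max(a, k))]
            db = dist[(min(b, k), max(b, k))]
            if linkage == "average":
                dn = (sa * da + sb * db) / (sa + sb)
            elif linkage == "complete":
                dn = max(da, db)
            else:
                dn = min(da, db)
            dist[(k, next_id)] = dn
        for key in list(dist):
            if a in key or b in key:
                del dist[key]
        del active[a], active[b]
        active[next_id] = (sa + sb, min(la, lb))
        next_id += 1
    return Dendrogram(labels=list(labels), merges=merges, linkage=linkage)


def cut_partition(dendrogram: Dendrogram, k: int) -> SpeciesPartition:
    """The k-cluster cut of a dendrogram (undo the last k-1 merges).

    Group labels are dense integers ordered by each group's lexically
    smallest member, so the labelling is deterministic.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} out of range 1..{n}")
    # replay the first n-k merges over leaf sets
    clusters: dict[int, set[int]] = {i: {i} for i in range(n)}
    for t in range(n - k):
        a, b, _ = dendrogram.merges[t]
        clusters[n + t] = clusters.pop(a) | clusters.pop(b)
    groups = sorted(
        clusters.values(),
        key=lambda s: min(dendrogram.labels[i] for i in s),
    )
    blocks: dict[str, int] = {}
    for g, members in enumerate(groups):
        for i in members:
            blocks[dendrogram.labels[i]] = g
    return SpeciesPartition(blocks=blocks)


def compare_partitions(
    p: SpeciesPartition, q: SpeciesPartition
) -> dict[str, float | bool]:
    """Adjusted Rand index and exact-match flag between two partitions."""
    if set(p.blocks) != set(q.blocks):
        raise ConsistencyError("partitions cover different individual sets")
    inds = sorted(p.blocks)
    ari = float(
        adjusted_rand_score(
            [p.blocks[i] for i in inds], [q.blocks[i] for i in inds]
        )
    )
    return {"ari": ari, "exact_match": p.as_sets() == q.as_sets()}


def render_heatmap(
    matrix: ConspecificityMatrix,
    dendrogram: Dendrogram,
    groups: SpeciesPartition | None,
    path: str | Path,
    distance_mode: str = "minmax-complement",
) -> None:
    """Render the clustered conspecificity heatmap with marginal dendrogram.

    The matrix is reordered by dendrogram leaf order and drawn on a
    diverging colour scale centred at zero; optional group boxes are drawn
    along both margins.  A JSON sidecar (same path + ``.json``) records the
    plotted leaf order, linkage, distance mode, colour limits, and group
    spans, so the figure is machine-checkable.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = dendrogram.leaf_order()
    idx = [dendrogram.labels.index(ind) for ind in order]
    c = matrix.score[np.ix_(idx, idx)].astype(float)
    np.fill_diagonal(c, np.nan)  # diagonal is presence count, not a score
    lim = np.nanmax(np.abs(c)) if np.isfinite(c).any() else 1.0
    lim = max(lim, 1.0)

    fig = plt.figure(figsize=(8, 8))
    gs = fig.add_gridspec(
        2, 1, height_ratios=[1, 4], hspace=0.03
    )
    ax_dend = fig.add_subplot(gs[0, 0])
    ax_heat = fig.add_subplot(gs[1, 0])

    # draw the dendrogram in the package's own deterministic leaf order
    if dendrogram.merges:
        n = dendrogram.n_leaves
        x_of = {dendrogram.labels.index(ind): float(k) for k, ind in enumerate(order)}
        h_of = {i: 0.0 for i in range(n)}
        children = {n + t: (a, b) for t, (a, b, _) in enumerate(dendrogram.merges)}

        def _x(cluster: int) -> float:
            if cluster in x_of:
                return x_of[cluster]
            a, b = children[cluster]
            x_of[cluster] = (_x(a) + _x(b)) / 2.0
            return x_of[cluster]

        for t, (a, b, h) in enumerate(dendrogram.merges):
            xa, xb = _x(a), _x(b)
            ax_dend.plot([xa, xa], [h_of[a], h], color="k", lw=0.8)
            ax_dend.plot([xb, xb], [h_of[b], h], color="k", lw=0.8)
            ax_dend.plot([xa, xb], [h, h], color="k", lw=0.8)
            h_of[n + t] = h
        ax_dend.set_xlim(-0.5, len(order) - 0.5)
    ax_dend.axis("off")

    im = ax_heat.imshow(
        c, cmap="RdBu_r", vmin=-lim, vmax=lim, aspect="auto",
        interpolation="nearest",
    )
    ax_heat.set_xticks(range(len(order)))
    ax_heat.set_xticklabels(order, rotation=90, fontsize=7)
    ax_heat.set_yticks(range(len(order)))
    ax_heat.set_yticklabels(order, fontsize=7)
    fig.colorbar(im, ax=ax_heat, shrink=0.6, label="conspecificity score")

    group_spans: list[dict] = []
    if groups is not None:
        palette = plt.get_cmap("tab10")
        seen_groups: list[int] = []
        for ind in order:
            g = groups.blocks[ind]
            if g not in seen_groups:
                seen_groups.append(g)
        start = 0
        while start < len(order):
            g = groups.blocks[order[start]]
            end = start
            while end + 1 < len(order) and groups.blocks[order[end + 1]] == g:
                end += 1
            color = palette(seen_groups.index(g) % 10)
            size = end - start + 1
            ax_heat.add_patch(
                plt.Rectangle(
                    (start - 0.5, start - 0.5), size, size,
                    fill=False, lw=2.5, edgecolor=color,
                )
            )
            group_spans.append(
                {"group": int(g), "start": start, "end": end,
                 "members": order[start : end + 1]}
            )
            start = end + 1

    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    sidecar = {
        "leaf_order": order,
        "linkage": dendrogram.linkage,
        "distance_mode": distance_mode,
        "vmin": -float(lim),
        "vmax": float(lim),
        "groups": group_spans,
    }
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)
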