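"""Eisen-style sample clustering: uncentered correlation + average linkage.

Similarity between two sample profiles x, y over the signature features is
the uncentered correlation ``s = (1/n) sum (x_i/s0_x)(y_i/s0_y)`` with
``s0_v = sqrt((1/n) sum v_i^2)`` — a cosine similarity that assumes a zero
reference level rather than centering each profile.  Distance is ``1 - s``
(range [0, 2]).  Agglomeration is UPGMA (average linkage): the recorded merge
height is the average pairwise inter-cluster distance, and ties are broken by
the lexicographically smallest pair of cluster indices in creation order,
which makes runs fully deterministic.  The two patient groups are the two
subtrees under the root merge, labelled HSC/LSC by mean anchor expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "uncentered_correlation_distance",
    "average_linkage",
    "cut_two",
    "Dendrogram",
    "ClusterAssignment",
]


def uncentered_correlation_distance(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Sample-by-sample distance matrix, d = 1 - uncentered correlation."""
    if len(matrix.sample_ids) < 2:
        raise ValueError("need at least 2 samples to cluster")
    X = matrix.values.T.astype(float)  # samples x features
    norms = np.sqrt((X**2).mean(axis=1))
    zero = norms == 0
    if zero.any():
        bad = [s for s, z in zip(matrix.sample_ids, zero) if z]
        raise ValueError(f"all-zero sample vector(s) over signature features: {bad}")
    Xn = X / norms[:, None]
    S = (Xn @ Xn.T) / X.shape[1]
    S = np.clip(S, -1.0, 1.0)
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0  # enforce exact symmetry against float jitter
    return pd.DataFrame(D, index=matrix.sample_ids, columns=matrix.sample_ids)


@dataclass
class Dendrogram:
    """Binary merge tree over samples.

    Leaves are numbered 0..n-1 in input order; merge k creates node n+k.
    ``merges`` holds (node_a, node_b, height) triples; heights are average
    linkage distances and are not guaranteed monotone.
    """

    merges: list  # [(int, int, float), ...], length n-1
    sample_ids: list

    @property
    def n_leaves(self) -> int:
        return len(self.sample_ids)

    def leaves_of(self, node: int) -> list[int]:
        """Leaf indices under a node, in creation order."""
        n = self.n_leaves
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < n:
                out.append(v)
            else:
                a, b, _ = self.merges[v - n]
                stack.extend((b, a))
        return out

    @property
    def leaf_order(self) -> list:
        """Sample identifiers in dendrogram (left-to-right) order."""
        root = self.n_leaves + len(self.merges) - 1
        return [self.sample_ids[i] for i in self.leaves_of(root)]

    def to_linkage(self) -> np.ndarray:
        """Convert to a scipy-style linkage matrix (for plotting)."""
        n = self.n_leaves
        sizes = {}
        Z = np.zeros((len(self.merges), 4))
        for k, (a, b, h) in enumerate(self.merges):
            sa = sizes.get(a, 1)
            sb = sizes.get(b, 1)
            sizes[n + k] = sa + sb
            Z[k] = (a, b, h, sa + sb)
        return Z


def average_linkage(dist) -> Dendrogram:
    """UPGMA agglomeration of a symmetric zero-diagonal distance matrix.

    Accepts a labelled DataFrame or a square ndarray.  At each step the pair
    of clusters with minimal average inter-cluster distance merges; among
    exact ties, the lexicographically smallest (i, j) pair of cluster indices
    (creation order) wins.
    """
    if isinstance(dist, pd.DataFrame):
        ids = list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        ids = list(range(D.shape[0]))
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.isfinite(D).all():
        raise ValueError("distance matrix must be finite")
    if not np.array_equal(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if n < 2:
        raise ValueError("need at least 2 samples")

    # inter-cluster average distances, keyed by frozenset-free (i, j) with i < j
    d = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        merges.append((a, b, h))
        for c in active - {a, b}:
            dac = d.pop((min(a, c), max(a, c)))
            dbc = d.pop((min(b, c), max(b, c)))
            d[(c, next_id)] = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
        del d[(a, b)]
        size[next_id] = size[a] + size[b]
        active -= {a, b}
        active.add(next_id)
        next_id += 1
    return Dendrogram(merges=merges, sample_ids=ids)


@dataclass
class ClusterAssignment:
    """HSC/LSC labels from the root split of a sample dendrogram."""

    labels: pd.Series  # "HSC" / "LSC" per sample
    anchor_means: dict  # label -> mean anchor expression
    dendrogram: Dendrogram

    @property
    def sample_ids(self) -> list:
        return list(self.labels.index)

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("label").to_frame()


def cut_two(dendrogram: Dendrogram, matrix: ExpressionMatrix, anchor_id) -> ClusterAssignment:
    """Cut the tree at the root into two clusters and label them by anchor level.

    The subtree with the higher mean anchor expression becomes HSC (high
    anchor cluster), the other LSC.  Exactly equal means are refused: the
    labelling would be arbitrary and needs a manual call.
    """
    if dendrogram.n_leaves < 2:
        raise ValueError("need at least 2 samples")
    a, b, _ = dendrogram.merges[-1]
    side_a = [dendrogram.sample_ids[i] for i in dendrogram.leaves_of(a)]
    side_b = [dendrogram.sample_ids[i] for i in dendrogram.leaves_of(b)]
    anchor = matrix.feature(anchor_id)
    mean_a = float(anchor[side_a].mean())
    mean_b = float(anchor[side_b].mean())
    if mean_a == mean_b:
        raise ValueError(
            "mean anchor expression identical in both subtrees; label clusters manually"
        )
    if mean_a > mean_b:
        hsc, lsc = side_a, side_b
        means = {"HSC": mean_a, "LSC": mean_b}
    else:
        hsc, lsc = side_b, side_a
        means = {"HSC": mean_b, "LSC": mean_a}
    labels = pd.Series("LSC", index=matrix.sample_ids, name="label")
    labels.loc[hsc] = "HSC"
    return ClusterAssignment(labels=labels, anchor_means=means, dendrogram=dendrogram)
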