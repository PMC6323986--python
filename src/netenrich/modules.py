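"""Network-module discovery: UPGMA clustering of a DSD matrix.

Tightly connected modules of an association network broadly correspond to
functional units, so a hierarchical clustering of the network's diffusion
state distances yields a data-driven classification framework covering
regions that curated pathway annotation may not reach.  The dendrogram is
built with unweighted average linkage (UPGMA) and every internal node
whose leaf set falls within a size window — 5 to 200 members by default —
is emitted as one gene set under the ``network_modules`` framework.

UPGMA is implemented here (Lance–Williams update) rather than delegated,
because the tie-break is part of the contract: when several cluster pairs
are at the minimal distance, the pair with the lexicographically smallest
(cluster-id, cluster-id) tuple merges first, with ids assigned in leaf
order then merge order.  This makes the dendrogram reproducible across
platforms.  On tie-free inputs the result agrees with any standard UPGMA
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dsd import DSDMatrix
from .errors import ValidationError
from .genesets import GeneSet, GeneSetCollection

__all__ = ["Merge", "Dendrogram", "hcluster_average", "extract_modules"]


@dataclass(frozen=True)
class Merge:
    """One agglomeration: clusters ``left`` and ``right`` join at
    ``height``; the new cluster has ``size`` leaves and id
    ``n_leaves + merge_index``."""

    left: int
    right: int
    height: float
    size: int


@dataclass(frozen=True)
class Dendrogram:
    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaves", tuple(self.leaves))
        object.__setattr__(self, "merges", tuple(self.merges))
        n = len(self.leaves)
        if len(self.merges) != n - 1:
            raise ValidationError(
                f"dendrogram over {n} leaves must have {n - 1} merges, "
                f"got {len(self.merges)}"
            )
        prev = -np.inf
        for k, m in enumerate(self.merges):
            if m.height < prev - 1e-9:
                raise ValidationError(
                    f"merge heights must be non-decreasing; merge {k} at "
                    f"{m.height} after {prev}"
                )
            prev = max(prev, m.height)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def member_sets(self) -> dict[int, frozenset[str]]:
        """Leaf-identifier sets of every cluster id (leaves and merges)."""
        n = len(self.leaves)
        members: dict[int, frozenset[str]] = {
            i: frozenset((name,)) for i, name in enumerate(self.leaves)
        }
        for k, m in enumerate(self.merges):
            members[n + k] = members[m.left] | members[m.right]
        return members

    def to_linkage(self) -> np.ndarray:
        """Scipy-style (n-1, 4) linkage array for interoperability."""
        return np.array(
            [[m.left, m.right, m.height, m.size] for m in self.merges], dtype=float
        )


def hcluster_average(d: DSDMatrix) -> Dendrogram:
    """Agglomerative clustering of a distance matrix with UPGMA linkage.

    Deterministic given the input; requires a symmetric, NaN-free matrix
    with at least two nodes (validated by :class:`DSDMatrix`).
    """
    n = len(d)
    if n < 2:
        raise ValidationError("clustering requires at least 2 nodes")
    dist = d.distances.astype(float).copy()
    if np.any(np.isnan(dist)):
        raise ValidationError("distance matrix contains NaN")

    # slot -> (current cluster id, leaf count); merged slots deactivated
    INF = np.inf
    np.fill_diagonal(dist, INF)
    ids = list(range(n))
    sizes = [1] * n
    active = np.ones(n, dtype=bool)
    merges: list[Merge] = []

    for step in range(n - 1):
        sub = dist[np.ix_(active, active)]
        mval = sub.min()
        # all active slot pairs achieving the minimum; pick the smallest
        # (cluster-id, cluster-id) pair
        act_idx = np.flatnonzero(active)
        ii, jj = np.nonzero(np.triu(sub <= mval, k=1))
        candidates = []
        for a, b in zip(ii, jj):
            sa, sb = act_idx[a], act_idx[b]
            pa, pb = sorted((ids[sa], ids[sb]))
            candidates.append(((pa, pb), sa, sb))
        (_, _), si, sj = min(candidates)

        new_id = n + step
        merges.append(Merge(min(ids[si], ids[sj]), max(ids[si], ids[sj]), float(mval),
                            sizes[si] + sizes[sj]))
        # Lance–Williams UPGMA update into slot si
        wi, wj = sizes[si], sizes[sj]
        row = (wi * dist[si] + wj * dist[sj]) / (wi + wj)
        dist[si], dist[:, si] = row, row
        dist[si, si] = INF
        active[sj] = False
        dist[sj], dist[:, sj] = INF, INF
        ids[si] = new_id
        sizes[si] = wi + wj

    return Dendrogram(tuple(d.nodes), tuple(merges))


def extract_modules(
    t: Dendrogram, min_size: int = 5, max_size: int = 200
) -> GeneSetCollection:
    """Emit every cluster of the dendrogram with size in [min_size, max_size].

    Clusters are taken from all hierarchy levels, so the emitted collection
    is multi-scale and may contain nested sets.  Duplicate member sets
    (possible when a merge adds nothing new after deduplication of inputs)
    keep their lowest-height instance.  Sets are labeled ``module_####`` in
    merge order with the linkage height in the description; the
    collection's framework label is ``"network_modules"``.
    """
    if min_size < 2:
        raise ValidationError(f"min_size must be >= 2, got {min_size}")
    if max_size < min_size:
        raise ValidationError(
            f"max_size ({max_size}) must be >= min_size ({min_size})"
        )
    members = t.member_sets()
    n = t.n_leaves
    seen: set[frozenset[str]] = set()
    sets: list[GeneSet] = []
    for k, m in enumerate(t.merges):
        mem = members[n + k]
        if not (min_size <= len(mem) <= max_size) or mem in seen:
            continue
        seen.add(mem)
        sets.append(
            GeneSet(
                id=f"module_{len(sets):04d}",
                description=f"height={m.height:.6g};size={len(mem)}",
                members=mem,
            )
        )
    return GeneSetCollection("network_modules", sets)
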