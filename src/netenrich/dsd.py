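"""Confidence-weighted diffusion state distance (DSD).

DSD measures how differently two nodes "see" the rest of the network
through random walks: with P the confidence-weighted random-walk
transition matrix, He_k(u) = sum_{t=0..k} e_u P^t collects the expected
visit counts of a k-step walk started at u, and

    DSD_k(u, v) = || He_k(u) - He_k(v) ||_1 .

As k -> infinity (on a connected, non-bipartite graph) the difference
converges, and the limit has the closed form

    DSD(u, v) = || (e_u - e_v) (I - P + W_pi)^{-1} ||_1 ,

where W_pi has every row equal to the stationary distribution pi of P.
The closed form is parameter-free and is the default here; the finite-k
accumulation is retained as an independent oracle.  DSD is a metric on a
connected component, and because P is invariant under uniform rescaling
of the edge weights, so is DSD.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import GraphConnectivityError, NumericalError, ValidationError
from .network import AssociationNetwork

__all__ = ["DSDMatrix", "transition_matrix", "dsd_matrix"]

#: Above this node count the linear system is solved column-by-column with
#: an iterative method instead of a dense inverse.
DENSE_LIMIT = 5000
ITERATIVE_TOL = 1e-8


class DSDMatrix:
    """Symmetric pairwise diffusion-state distances with a node order."""

    def __init__(self, nodes: list[str], distances: np.ndarray):
        distances = np.asarray(distances, dtype=float)
        n = len(nodes)
        if distances.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {distances.shape} does not match "
                f"{n} nodes"
            )
        if not np.all(np.isfinite(distances)):
            raise ValidationError("distance matrix contains non-finite entries")
        if not np.allclose(distances, distances.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(distances < 0) or np.any(np.abs(np.diag(distances)) > 1e-12):
            raise ValidationError("distances must be >= 0 with a zero diagonal")
        self.nodes = list(nodes)
        # exact symmetry and zero diagonal after numerical solves
        d = 0.5 * (distances + distances.T)
        np.fill_diagonal(d, 0.0)
        self.distances = d

    def __len__(self) -> int:
        return len(self.nodes)

    def get(self, u: str, v: str) -> float:
        i, j = self.nodes.index(u), self.nodes.index(v)
        return float(self.distances[i, j])

    def to_tsv(self, path) -> None:
        """Write as TSV with node identifiers as header row and first column."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\t".join([""] + self.nodes) + "\n")
            for name, row in zip(self.nodes, self.distances):
                fh.write(name + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DSDMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            rows = []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in fields[1:]])
        return cls(header, np.array(rows))


def _node_order(net: AssociationNetwork) -> list[str]:
    return sorted(net.nodes)


def transition_matrix(net: AssociationNetwork) -> tuple[list[str], np.ndarray]:
    """Row-stochastic random-walk matrix weighted by combined confidences.

    Entry (i, j) is w(i, j) / sum_k w(i, k).  Requires a connected network
    with at least two nodes; on an isolated node or a disconnected graph a
    :class:`GraphConnectivityError` is raised instructing the caller to
    restrict to the largest connected component
    (:meth:`AssociationNetwork.largest_connected_component`).
    """
    nodes = _node_order(net)
    n = len(nodes)
    if n < 2:
        raise ValidationError("transition matrix requires at least 2 nodes")
    index = {name: i for i, name in enumerate(nodes)}
    w = np.zeros((n, n))
    for e in net.edges:
        i, j = index[e.protein_a], index[e.protein_b]
        w[i, j] = w[j, i] = e.combined
    deg = w.sum(axis=1)
    if np.any(deg == 0):
        isolated = nodes[int(np.argmin(deg))]
        raise GraphConnectivityError(
            f"node {isolated!r} is isolated (zero total edge weight); "
            "restrict the network to its largest connected component first"
        )
    import networkx as nx

    if not nx.is_connected(net.to_networkx()):
        raise GraphConnectivityError(
            "network is disconnected; restrict it to its largest connected "
            "component first (AssociationNetwork.largest_connected_component)"
        )
    return nodes, w / deg[:, None]


def _visit_counts(P: np.ndarray, steps: int) -> np.ndarray:
    """Rows are He_k(u): expected visit counts of a k-step walk from u."""
    n = P.shape[0]
    M = np.eye(n)
    H = np.eye(n)
    for _ in range(steps):
        M = M @ P
        H += M
    return H


def dsd_matrix(net: AssociationNetwork, steps: int | str = "converged") -> DSDMatrix:
    """Compute the diffusion state distance matrix of a connected network.

    ``steps`` is a positive integer (finite-k walk) or ``"converged"``
    (default), which evaluates the closed-form limit via a linear solve.
    """
    nodes, P = transition_matrix(net)
    n = len(nodes)
    if steps == "converged":
        acc = {u: 0.0 for u in nodes}
        for e in net.edges:
            acc[e.protein_a] += e.combined
            acc[e.protein_b] += e.combined
        deg = np.array([acc[u] for u in nodes])
        pi = deg / deg.sum()  # stationary distribution of a reversible walk
        A = np.eye(n) - P + np.tile(pi, (n, 1))
        if n <= DENSE_LIMIT:
            try:
                X = np.linalg.inv(A)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(
                    f"(I - P + W_pi) is singular on a {n}-node connected "
                    f"graph: {exc}"
                ) from exc
        else:
            X = _rows_of_inverse_iterative(A)
        profiles = X
    else:
        if not (isinstance(steps, (int, np.integer)) and steps > 0):
            raise ValidationError(
                f"steps must be a positive integer or 'converged', got {steps!r}"
            )
        profiles = _visit_counts(P, int(steps))
    d = squareform(pdist(profiles, metric="cityblock"))
    return DSDMatrix(nodes, d)


def _rows_of_inverse_iterative(A: np.ndarray) -> np.ndarray:
    """Rows of A^{-1} via per-column iterative solves of A^T y = e_u."""
    from scipy.sparse.linalg import lgmres

    n = A.shape[0]
    At = A.T.copy()
    X = np.empty((n, n))
    for u in range(n):
        e = np.zeros(n)
        e[u] = 1.0
        y, info = lgmres(At, e, rtol=ITERATIVE_TOL, atol=0.0)
        if info != 0:
            raise NumericalError(f"iterative solve failed for node index {u} (info={info})")
        X[u] = y
    return X
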