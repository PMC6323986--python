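"""Synthetic fixtures: planted-partition networks and planted-signal values.

Real organism-scale association networks and genome-wide measurements are
large downloads; for testing every stage end-to-end this module generates
stand-ins with known ground truth.

Networks follow the planted-partition model: nodes are grouped into
blocks, within-block pairs get an edge with probability ``p_in`` and
between-block pairs with ``p_out``; edge confidences are drawn from a
high-mode Beta for within-block edges and a low-mode Beta for
between-block edges, mimicking the shape of confidence scores without
claiming any empirical distribution.  Value tables plant an enrichment
signal: background genes draw values from Normal(0, sd) and a planted set
from Normal(delta, sd).

All outputs are bit-reproducible given the spec and seed; the seed is
mandatory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .enrichment import GeneValueTable
from .errors import ValidationError
from .network import Association, AssociationNetwork, ChannelScores

logger = logging.getLogger("netenrich")

__all__ = ["PlantedSpec", "make_modular_network", "make_value_table"]


@dataclass(frozen=True)
class PlantedSpec:
    """Parameters of a planted-partition network with confidence weights.

    ``block_sizes`` may sum to less than ``n_nodes``; leftover nodes are
    background (no block).  ``weight_in`` / ``weight_out`` are Beta(a, b)
    shape pairs for within-/between-block edge confidences, clipped to
    (0, 1].
    """

    n_nodes: int
    block_sizes: tuple[int, ...]
    p_in: float = 0.8
    p_out: float = 0.05
    weight_in: tuple[float, float] = (6.0, 2.0)
    weight_out: tuple[float, float] = (2.0, 6.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("PlantedSpec.seed is mandatory")
        if self.n_nodes < 2:
            raise ValidationError("n_nodes must be >= 2")
        if sum(self.block_sizes) > self.n_nodes:
            raise ValidationError("block sizes must sum to <= n_nodes")
        for p, name in ((self.p_in, "p_in"), (self.p_out, "p_out")):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {p}")


def _node_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def make_modular_network(
    spec: PlantedSpec,
) -> tuple[AssociationNetwork, list[set[str]]]:
    """Generate a planted-partition association network.

    Returns the largest connected component of the sampled graph together
    with the planted blocks restricted to it (trimming is logged).  The
    edge confidence is stored both as the combined score and in the
    experiments channel.
    """
    rng = np.random.default_rng(spec.seed)
    names = _node_names(spec.n_nodes)
    block_of = np.full(spec.n_nodes, -1)
    start = 0
    for b, size in enumerate(spec.block_sizes):
        block_of[start : start + size] = b
        start += size

    iu, ju = np.triu_indices(spec.n_nodes, k=1)
    same = (block_of[iu] >= 0) & (block_of[iu] == block_of[ju])
    p_edge = np.where(same, spec.p_in, spec.p_out)
    present = rng.random(iu.size) < p_edge
    a_in, b_in = spec.weight_in
    a_out, b_out = spec.weight_out
    w = np.where(
        same, rng.beta(a_in, b_in, size=iu.size), rng.beta(a_out, b_out, size=iu.size)
    )
    w = np.clip(w, 1e-6, 1.0)

    net = AssociationNetwork(nodes=names)
    for i, j, keep, wij in zip(iu, ju, present, w):
        if not keep:
            continue
        wij = float(wij)
        net.add_association(
            Association(
                names[i], names[j],
                channels=ChannelScores(experiments=wij),
                combined=wij,
            )
        )
    if net.n_edges == 0:
        raise ValidationError("spec yielded a graph with no edges")

    lcc = net.largest_connected_component()
    blocks = []
    for b in range(len(spec.block_sizes)):
        members = {names[i] for i in np.flatnonzero(block_of == b)} & lcc.nodes
        blocks.append(members)
    dropped = spec.n_nodes - lcc.n_nodes
    if dropped:
        logger.warning(
            "planted network: %d node(s) outside the largest component dropped",
            dropped,
        )
    return lcc, blocks


def make_value_table(
    genes: Iterable[str],
    planted: Iterable[str],
    delta: float,
    sd: float,
    seed: int,
) -> GeneValueTable:
    """Gene-value table with a planted mean shift.

    Background genes draw from Normal(0, sd), planted genes from
    Normal(delta, sd).  ``planted`` must be a subset of ``genes``; order
    of the inputs does not affect the output (genes are sorted before
    sampling).
    """
    genes = sorted(set(genes))
    planted = set(planted)
    if not planted <= set(genes):
        missing = sorted(planted - set(genes))[:5]
        raise ValidationError(f"planted genes not in universe, e.g. {missing}")
    if not sd > 0:
        raise ValidationError(f"sd must be > 0, got {sd}")
    rng = np.random.default_rng(seed)
    vals = rng.normal(0.0, sd, size=len(genes))
    values = {}
    for g, x in zip(genes, vals):
        values[g] = float(x + delta) if g in planted else float(x)
    return GeneValueTable(values)
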