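"""Channel-scored protein association networks.

A functional association links two proteins that contribute jointly to a
specific biological function; it need not be a physical contact.  Evidence
for an association is split across seven independent channels (genomic
neighborhood, gene fusion, co-occurrence, co-expression, experiments,
curated databases, text-mining), each scored as an approximate confidence
on a scale of zero to one.  Channels may additionally carry a "transferred"
sub-score for evidence propagated from other organisms.

This module provides the in-memory model (:class:`ChannelScores`,
:class:`Association`, :class:`AssociationNetwork`), TSV edge-list I/O in
both the integer 0–1000 download dialect and a plain float 0–1 dialect,
probabilistic channel combination, the uniform curated-database channel
scoring rule, and confidence filtering with named presets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import ConfigError, ParseError, ValidationError

logger = logging.getLogger("netenrich")

#: The seven evidence channels, in canonical order.
CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experiments",
    "databases",
    "textmining",
)

#: Uniform confidence assigned to every curated-database association.
DATABASE_CHANNEL_SCORE = 0.900

#: Named confidence cutoffs.  Only "highest" is a published constant; the
#: others are conventional defaults and may be overridden by the caller.
CONFIDENCE_PRESETS = {
    "highest": 0.900,
    "high": 0.700,
    "medium": 0.400,
    "low": 0.150,
}

# Column-name aliases seen in download files -> canonical channel names.
_COLUMN_ALIASES = {
    "cooccurence": "cooccurrence",
    "experimental": "experiments",
    "database": "databases",
}
_COMBINED_NAMES = {"combined_score", "combined", "score", "weight"}


def _check_unit_interval(name: str, value: float) -> None:
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be a finite confidence in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ChannelScores:
    """Per-channel confidences in [0, 1]; absent evidence is 0, never missing.

    ``transferred`` optionally holds inter-organism sub-scores, keyed by
    channel name.  Within a channel, direct and transferred sub-scores are
    merged by noisy-OR (a convention; see :meth:`merged`).
    """

    neighborhood: float = 0.0
    fusion: float = 0.0
    cooccurrence: float = 0.0
    coexpression: float = 0.0
    experiments: float = 0.0
    databases: float = 0.0
    textmining: float = 0.0
    transferred: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            _check_unit_interval(ch, getattr(self, ch))
        if self.transferred is not None:
            for ch, v in self.transferred.items():
                if ch not in CHANNELS:
                    raise ConfigError(f"unknown channel in transferred sub-scores: {ch!r}")
                _check_unit_interval(f"transferred {ch}", v)

    def merged(self, channel: str) -> float:
        """Direct and transferred sub-scores of one channel, noisy-OR merged."""
        if channel not in CHANNELS:
            raise ConfigError(f"unknown channel: {channel!r}")
        direct = getattr(self, channel)
        if self.transferred is None:
            return direct
        t = self.transferred.get(channel, 0.0)
        return 1.0 - (1.0 - direct) * (1.0 - t)


@dataclass(frozen=True)
class Association:
    """One undirected association; endpoints are stored canonicalized
    (lexicographically smaller identifier first)."""

    protein_a: str
    protein_b: str
    channels: ChannelScores = field(default_factory=ChannelScores)
    combined: float = 0.0

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise ValidationError(f"self-association not allowed: {self.protein_a!r}")
        if self.protein_a > self.protein_b:
            a, b = self.protein_a, self.protein_b
            object.__setattr__(self, "protein_a", b)
            object.__setattr__(self, "protein_b", a)
        _check_unit_interval("combined", self.combined)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class AssociationNetwork:
    """Undirected weighted graph of proteins with at most one association
    per unordered pair; nodes may be isolated."""

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[Association] = ()):
        self.nodes: set[str] = set(nodes)
        self._edges: dict[tuple[str, str], Association] = {}
        for e in edges:
            self.add_association(e)

    def add_node(self, node: str) -> None:
        self.nodes.add(node)

    def add_association(self, assoc: Association) -> None:
        self.nodes.add(assoc.protein_a)
        self.nodes.add(assoc.protein_b)
        self._edges[assoc.pair] = assoc

    @property
    def edges(self) -> list[Association]:
        return [self._edges[k] for k in sorted(self._edges)]

    def get(self, a: str, b: str) -> Association | None:
        return self._edges.get(_canonical_pair(a, b))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self._edges.values():
            g.add_edge(e.protein_a, e.protein_b, weight=e.combined, association=e)
        return g

    def largest_connected_component(self) -> "AssociationNetwork":
        """Restriction to the largest connected component (ties broken by
        smallest member identifier)."""
        g = self.to_networkx()
        if g.number_of_nodes() == 0:
            return AssociationNetwork()
        comps = sorted(nx.connected_components(g), key=lambda c: (-len(c), min(c)))
        keep = comps[0]
        sub = AssociationNetwork(nodes=keep)
        for e in self._edges.values():
            if e.protein_a in keep:
                sub.add_association(e)
        if len(keep) < self.n_nodes:
            logger.warning(
                "restricted to largest connected component: kept %d of %d nodes",
                len(keep), self.n_nodes,
            )
        return sub


def combine_channels(
    c: ChannelScores,
    enabled: Iterable[str] | None = None,
    prior: float = 0.0,
) -> float:
    """Integrate per-channel confidences into one combined confidence.

    Each enabled channel score (direct/transferred noisy-OR merged) has the
    prior removed, ``(s - p) / (1 - p)`` floored at 0; the corrected scores
    are combined by noisy-OR, ``1 - prod(1 - s_i)``, and the prior is
    re-added.  With ``prior == 0`` this is a plain noisy-OR, so a single
    enabled channel passes through unchanged and the result never falls
    below the largest enabled channel score.
    """
    if not 0.0 <= prior < 1.0:
        raise ConfigError(f"prior must be in [0, 1), got {prior!r}")
    names = tuple(CHANNELS if enabled is None else enabled)
    if not names:
        raise ConfigError("at least one channel must be enabled")
    for ch in names:
        if ch not in CHANNELS:
            raise ConfigError(f"unknown channel: {ch!r}")
    prod = 1.0
    for ch in names:
        s = c.merged(ch)
        s_np = max(0.0, (s - prior) / (1.0 - prior))
        prod *= 1.0 - s_np
    combined_np = 1.0 - prod
    return combined_np * (1.0 - prior) + prior


def score_database_channel(
    records: Iterable[tuple[str, str]],
) -> list[tuple[tuple[str, str], float]]:
    """Score curated pathway/complex co-membership records.

    Curated knowledge needs no statistical calibration: every distinct
    protein pair named by the records receives the uniform confidence
    0.900.  Duplicate records (including the same pair from different
    source databases) collapse to one association; self-pairs are skipped
    with a warning.  Output is sorted by pair.
    """
    pairs: set[tuple[str, str]] = set()
    for a, b in records:
        if a == b:
            logger.warning("skipping self-pair curated record: %r", a)
            continue
        pairs.add(_canonical_pair(a, b))
    return [(p, DATABASE_CHANNEL_SCORE) for p in sorted(pairs)]


def filter_by_confidence(
    net: AssociationNetwork, cutoff: float | str
) -> AssociationNetwork:
    """Keep associations with combined confidence >= cutoff.

    ``cutoff`` may be a number in [0, 1] or a preset name
    (:data:`CONFIDENCE_PRESETS`).  The node set is unchanged, so filtering
    can leave isolated nodes.  Idempotent.
    """
    if isinstance(cutoff, str):
        try:
            cutoff = CONFIDENCE_PRESETS[cutoff]
        except KeyError:
            raise ConfigError(
                f"unknown confidence preset {cutoff!r}; "
                f"known presets: {sorted(CONFIDENCE_PRESETS)}"
            ) from None
    if not 0.0 <= cutoff <= 1.0:
        raise ConfigError(f"confidence cutoff must be in [0, 1], got {cutoff!r}")
    out = AssociationNetwork(nodes=net.nodes)
    for e in net.edges:
        if e.combined >= cutoff:
            out.add_association(e)
    return out


# ---------------------------------------------------------------------------
# TSV edge-list I/O
# ---------------------------------------------------------------------------

def _parse_score(raw: str, lineno: int, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric score {raw!r} in column {col!r}") from None


def read_network(path, dialect: str = "auto") -> AssociationNetwork:
    """Read a TSV edge list into an :class:`AssociationNetwork`.

    The file must have a header naming two protein columns followed by one
    or more score columns ('#'-prefixed comment lines are ignored).  Score
    columns matching channel names populate :class:`ChannelScores`; a
    column named ``combined_score`` (or ``combined``/``score``/``weight``)
    is the combined confidence.  If no combined column is present it is
    computed from the channels by noisy-OR.

    ``dialect`` is ``"string1000"`` (integer scores 0–1000, divided by
    1000), ``"float"`` (scores already in [0, 1]), or ``"auto"``, which
    picks string1000 iff any score exceeds 1.
    """
    if dialect not in ("auto", "string1000", "float"):
        raise ConfigError(f"unknown dialect {dialect!r}")

    with open(path, encoding="utf-8") as fh:
        raw_lines = fh.readlines()

    lines: list[tuple[int, list[str]]] = []
    for i, ln in enumerate(raw_lines, start=1):
        ln = ln.rstrip("\n")
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        lines.append((i, ln.split("\t")))
    if not lines:
        raise ParseError(f"{path}: empty network file (no header)")

    header_lineno, header = lines[0]
    header = [h.strip() for h in header]
    if len(header) < 3:
        raise ParseError(
            f"line {header_lineno}: header must name two protein columns "
            f"and at least one score column, got {header!r}"
        )
    score_cols = []
    for idx, name in enumerate(header[2:], start=2):
        canon = _COLUMN_ALIASES.get(name.lower(), name.lower())
        if canon in CHANNELS:
            score_cols.append((idx, canon))
        elif canon in _COMBINED_NAMES:
            score_cols.append((idx, "combined"))
        else:
            raise ParseError(
                f"line {header_lineno}: unrecognized score column {name!r}; "
                f"expected channel names or 'combined_score'"
            )
    if len(score_cols) == 1 and score_cols[0][1] != "combined":
        # a single score column is taken as the combined confidence
        score_cols = [(score_cols[0][0], "combined")]

    rows: list[tuple[int, str, str, dict[str, float]]] = []
    max_seen = 0.0
    for lineno, fields in lines[1:]:
        if len(fields) != len(header):
            raise ParseError(
                f"line {lineno}: expected {len(header)} tab-separated fields, "
                f"got {len(fields)}"
            )
        a, b = fields[0].strip(), fields[1].strip()
        scores = {}
        for idx, name in score_cols:
            v = _parse_score(fields[idx].strip(), lineno, header[idx])
            scores[name] = v
            max_seen = max(max_seen, v)
        rows.append((lineno, a, b, scores))

    if dialect == "auto":
        dialect = "string1000" if max_seen > 1.0 else "float"
    scale = 1000.0 if dialect == "string1000" else 1.0
    hi = 1000.0 if dialect == "string1000" else 1.0

    net = AssociationNetwork()
    for lineno, a, b, scores in rows:
        for name, v in scores.items():
            if not 0.0 <= v <= hi:
                raise ParseError(
                    f"line {lineno}: score {v!r} outside [0, {hi:g}] "
                    f"({dialect} dialect)"
                )
        if a == b:
            logger.warning("line %d: skipping self-loop %r", lineno, a)
            net.add_node(a)
            continue
        norm = {k: v / scale for k, v in scores.items()}
        combined = norm.pop("combined", None)
        channels = ChannelScores(**norm)
        if combined is None:
            combined = combine_channels(channels)
        assoc = Association(a, b, channels=channels, combined=combined)
        prev = net.get(a, b)
        if prev is not None and prev.combined != assoc.combined:
            logger.warning(
                "line %d: duplicate pair %s-%s with differing scores; keeping max",
                lineno, *assoc.pair,
            )
            if prev.combined >= assoc.combined:
                continue
        net.add_association(assoc)
    return net


def write_network(
    net: AssociationNetwork,
    path,
    dialect: str = "float",
    channels: bool = True,
) -> None:
    """Write a TSV edge list (``protein1``, ``protein2``, per-channel
    scores, ``combined_score``).  The string1000 dialect emits integers
    (score * 1000 rounded), bit-exact on round-trip for scores that were
    read from that dialect."""
    if dialect not in ("string1000", "float"):
        raise ConfigError(f"unknown dialect {dialect!r}")

    def fmt(v: float) -> str:
        return str(round(v * 1000)) if dialect == "string1000" else f"{v:.6f}"

    cols = ["protein1", "protein2"]
    if channels:
        cols += list(CHANNELS)
    cols.append("combined_score")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in net.edges:
            row = [e.protein_a, e.protein_b]
            if channels:
                row += [fmt(getattr(e.channels, ch)) for ch in CHANNELS]
            row.append(fmt(e.combined))
            fh.write("\t".join(row) + "\n")
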