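"""Gene-set collections ("classification frameworks") and their I/O.

A classification framework is a coherent collection of gene sets — GO
terms, KEGG pathways, network modules, or per-publication gene lists —
within which multiple-testing correction is later applied separately.
Supported formats: Broad-dialect GMT (one set per line: id, description,
members...) and two-column mapping TSV (set id, gene), the latter for
publication-to-gene mappings where each publication becomes one set.

Gene identifier matching throughout the package is exact-string and
case-sensitive: mismatched identifier namespaces must fail loudly rather
than silently shrink sets.  An optional uppercase normalization hook is
available on the readers for callers who know their namespaces agree up
to case.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from .errors import ParseError, ValidationError

logger = logging.getLogger("netenrich")


@dataclass(frozen=True)
class GeneSet:
    id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError(f"gene set {self.id!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class GeneSetCollection:
    framework: str
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.framework:
            raise ValidationError("framework label must be non-empty")
        seen: set[str] = set()
        for s in self.sets:
            if s.id in seen:
                raise ValidationError(
                    f"duplicate gene-set id {s.id!r} in framework {self.framework!r}"
                )
            seen.add(s.id)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.framework == other.framework and self.sets == other.sets

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets:
            out |= s.members
        return out


def read_gmt(path, framework: str | None = None, uppercase: bool = False) -> GeneSetCollection:
    """Read a GMT file; the framework label defaults to the filename stem."""
    path = Path(path)
    if framework is None:
        framework = path.stem
    sets: list[GeneSet] = []
    first_line: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"line {lineno}: GMT line needs id, description and at "
                    f"least one member, got {len(fields)} field(s)"
                )
            sid, desc, *members = fields
            members = [m.strip() for m in members if m.strip()]
            if not members:
                raise ParseError(f"line {lineno}: gene set {sid!r} has an empty member list")
            if uppercase:
                members = [m.upper() for m in members]
            if sid in first_line:
                raise ParseError(
                    f"duplicate gene-set id {sid!r} on lines "
                    f"{first_line[sid]} and {lineno}"
                )
            first_line[sid] = lineno
            sets.append(GeneSet(sid, desc, frozenset(members)))
    return GeneSetCollection(framework, sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write GMT; members canonicalized lexicographically."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.id, s.description] + sorted(s.members)) + "\n")


def load_mapping_sets(path, framework: str, uppercase: bool = False) -> GeneSetCollection:
    """Load a two-column (set id, gene) TSV, grouping rows into sets.

    Typical use: publication-identifier -> gene mappings, one gene set per
    publication.  Singleton sets are retained; downstream callers may
    filter.  Repeated rows store a member once.
    """
    groups: dict[str, set[str]] = {}
    order: list[str] = []
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"line {lineno}: mapping rows must have exactly two "
                    f"tab-separated columns, got {len(fields)}"
                )
            sid, gene = fields[0].strip(), fields[1].strip()
            if uppercase:
                gene = gene.upper()
            if sid not in groups:
                groups[sid] = set()
                order.append(sid)
            groups[sid].add(gene)
            n_rows += 1
    if n_rows == 0:
        logger.warning("%s: empty mapping file; returning empty collection", path)
    sets = [GeneSet(sid, "", frozenset(groups[sid])) for sid in order]
    return GeneSetCollection(framework, sets)
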