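"""NCBI-style taxonomy handling: dump parsing, merged-ID resolution, rank projection.

The evaluation iterates over the eight major taxonomic ranks, from superkingdom
down to species. Sub-species nodes (rank "strain", "no rank", ...) are reached
only through projection onto a major rank and never keyed on directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ParseError, StructuralError, UnknownTaxonError

logger = logging.getLogger(__name__)

#: The eight major ranks used throughout the evaluation, most general first.
#: With unit branch lengths and a virtual root joining superkingdoms, a species
#: node sits at depth 8, which fixes the worst-case weighted UniFrac at 16.
MAJOR_RANKS: tuple[str, ...] = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


@dataclass
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str = ""


@dataclass
class TaxonomyDB:
    """Rooted taxonomic tree with merged-ID aliases.

    Attributes
    ----------
    nodes
        Map taxid -> :class:`TaxNode` (parent pointer, rank, scientific name).
    merged
        Map of retired taxid -> current taxid.
    major_ranks
        Ordered rank names, most general to most specific; length 8, ending
        with ``"species"`` by default.
    """

    nodes: dict[int, TaxNode] = field(default_factory=dict)
    merged: dict[int, int] = field(default_factory=dict)
    major_ranks: tuple[str, ...] = MAJOR_RANKS

    def __post_init__(self):
        self.major_ranks = tuple(self.major_ranks)
        self._rank_index = {r: i for i, r in enumerate(self.major_ranks)}

    @property
    def root(self) -> int:
        roots = [t for t, n in self.nodes.items() if n.parent == t]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root node, found {len(roots)}")
        return roots[0]

    def validate(self) -> None:
        """Check the structural invariants: single root, closed parent pointers, no cycles."""
        _ = self.root
        for taxid, node in self.nodes.items():
            if node.parent not in self.nodes:
                raise StructuralError(
                    f"node {taxid} lists parent {node.parent} absent from the taxonomy"
                )
        # Cycle check by walking every lineage with a visited budget.
        for taxid in self.nodes:
            seen = set()
            cur = taxid
            while self.nodes[cur].parent != cur:
                if cur in seen:
                    raise StructuralError(f"cyclic parent chain involving taxon {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def resolve(self, taxid: int) -> int:
        """Map a possibly retired taxon ID to its current ID.

        Chains of merges are followed until an ID present in ``nodes`` is
        reached. Raises :class:`UnknownTaxonError` if the ID is in neither
        table.
        """
        if taxid in self.nodes:
            return taxid
        cur = taxid
        seen = set()
        while cur in self.merged:
            if cur in seen:
                raise StructuralError(f"cyclic merged-ID chain at {cur}")
            seen.add(cur)
            cur = self.merged[cur]
            if cur in self.nodes:
                return cur
        raise UnknownTaxonError(taxid)

    def lineage(self, taxid: int) -> list[int]:
        """Root-to-self chain of taxon IDs (inclusive)."""
        cur = self.resolve(taxid)
        chain = [cur]
        while self.nodes[cur].parent != cur:
            cur = self.nodes[cur].parent
            chain.append(cur)
        return chain[::-1]

    def project_to_rank(self, taxid: int, rank: str) -> int | None:
        """First ancestor-or-self of ``taxid`` whose rank equals ``rank``.

        Returns ``None`` when the lineage has no node at that rank (common for
        incompletely annotated clades). ``rank`` must be a major rank.
        """
        if rank not in self._rank_index:
            raise ValueError(f"rank {rank!r} is not a major rank {self.major_ranks}")
        cur = self.resolve(taxid)
        while True:
            if self.nodes[cur].rank == rank:
                return cur
            parent = self.nodes[cur].parent
            if parent == cur:
                return None
            cur = parent

    def depth_map(self) -> dict[int, int]:
        """Depth of every node counting unit-length edges from the root (root = 0)."""
        depths: dict[int, int] = {}

        def depth(t: int) -> int:
            if t in depths:
                return depths[t]
            node = self.nodes[t]
            d = 0 if node.parent == t else depth(node.parent) + 1
            depths[t] = d
            return d

        for t in self.nodes:
            depth(t)
        return depths


def _iter_dmp(path: Path) -> Iterable[tuple[int, list[str]]]:
    # NCBI dump rows are "field\t|\tfield\t|\t...\t|"
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.rstrip("|\t ").split("\t|\t")]
            yield lineno, fields


def load_taxonomy(
    nodes_path,
    names_path,
    merged_path=None,
    major_ranks: tuple[str, ...] = MAJOR_RANKS,
) -> TaxonomyDB:
    """Parse NCBI-format ``nodes.dmp``/``names.dmp`` (and optionally ``merged.dmp``).

    Only rows of name class ``scientific name`` are taken from ``names.dmp``.
    Unknown rank strings are preserved verbatim. The returned database is
    validated (single root, closed parents, acyclic).
    """
    db = TaxonomyDB(major_ranks=major_ranks)
    for lineno, fields in _iter_dmp(Path(nodes_path)):
        if len(fields) < 3:
            raise ParseError(
                f"nodes row needs >=3 pipe-delimited fields, got {len(fields)}",
                path=nodes_path,
                line=lineno,
            )
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as e:
            raise ParseError(f"non-integer taxon ID: {e}", path=nodes_path, line=lineno)
        db.nodes[taxid] = TaxNode(taxid=taxid, parent=parent, rank=fields[2])

    for lineno, fields in _iter_dmp(Path(names_path)):
        if len(fields) < 4:
            raise ParseError(
                f"names row needs 4 pipe-delimited fields, got {len(fields)}",
                path=names_path,
                line=lineno,
            )
        if fields[3] != "scientific name":
            continue
        try:
            taxid = int(fields[0])
        except ValueError as e:
            raise ParseError(f"non-integer taxon ID: {e}", path=names_path, line=lineno)
        if taxid in db.nodes:
            db.nodes[taxid].name = fields[1]

    if merged_path is not None:
        for lineno, fields in _iter_dmp(Path(merged_path)):
            if len(fields) < 2:
                raise ParseError(
                    "merged row needs 2 pipe-delimited fields", path=merged_path, line=lineno
                )
            try:
                db.merged[int(fields[0])] = int(fields[1])
            except ValueError as e:
                raise ParseError(f"non-integer taxon ID: {e}", path=merged_path, line=lineno)

    db.validate()
    return db


def resolve_taxid(db: TaxonomyDB, taxid: int) -> int:
    """Functional alias for :meth:`TaxonomyDB.resolve`."""
    return db.resolve(taxid)


def project_to_rank(db: TaxonomyDB, taxid: int, rank: str) -> int | None:
    """Functional alias for :meth:`TaxonomyDB.project_to_rank`."""
    return db.project_to_rank(taxid, rank)
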