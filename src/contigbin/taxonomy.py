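"""NCBI-dump-style taxonomy handling.

Parses ``nodes.dmp`` / ``names.dmp`` dialect files into a rooted
:class:`TaxonomyTree` and answers the queries the binning stages need:
lineages, rank-level ancestors, lowest common ancestors (LCA), and the
"uncultured / unidentified" name-exclusion test used when deriving
taxonomy from rRNA best hits.

The dump dialect is the NCBI taxonomy one: fields separated by
``\\t|\\t`` with records terminated by ``\\t|``.  Toy fixtures that use a
bare ``|`` separator with surrounding whitespace are accepted too; every
field is stripped after splitting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

__all__ = [
    "TaxonNode",
    "TaxonomyTree",
    "TaxonomyError",
    "parse_taxonomy",
    "is_excluded_name",
    "DEFAULT_EXCLUSION_TERMS",
]

#: Name substrings that disqualify a subject from best-hit taxonomy
#: assignment (matched case-insensitively).
DEFAULT_EXCLUSION_TERMS: tuple[str, ...] = (
    "uncultured",
    "unidentified",
    "environmental sample",
    "metagenome",
)


class TaxonomyError(ValueError):
    """Raised for malformed dumps or invalid taxid queries."""


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: identifier, parent link, rank and scientific name.

    The root follows the NCBI convention of being its own parent
    (taxid 1 has parent_taxid 1).
    """

    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str

    def __post_init__(self) -> None:
        if self.taxid < 1:
            raise TaxonomyError(f"taxid must be >= 1, got {self.taxid}")
        if not self.scientific_name:
            raise TaxonomyError(f"taxid {self.taxid} has an empty scientific name")


def _dmp_fields(line: str) -> list[str]:
    """Split one dump record into stripped fields.

    Handles both the canonical ``\\t|\\t`` separator and loose ``|``
    separation; the trailing record terminator yields an empty last
    field, which is dropped.
    """
    parts = [f.strip() for f in line.rstrip("\n").split("|")]
    if parts and parts[-1] == "":
        parts.pop()
    return parts


def _as_lines(stream: str | Path | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(stream, (str, Path)):
        path = Path(stream)
        if path.exists():
            with open(path, "rt", encoding="utf-8") as fh:
                yield from fh
            return
        if isinstance(stream, str):
            # Treat a non-path string as literal dump text.
            yield from io.StringIO(stream)
            return
        raise FileNotFoundError(str(stream))
    else:
        yield from stream


class TaxonomyTree:
    """Rooted taxonomy over a ``taxid -> TaxonNode`` map.

    Construction validates the structural invariants: exactly one
    self-parented root, every parent present, and no cycles.
    """

    def __init__(self, nodes: Mapping[int, TaxonNode]):
        self.nodes: dict[int, TaxonNode] = dict(nodes)
        if not self.nodes:
            raise TaxonomyError("taxonomy has no nodes")
        roots = [n.taxid for n in self.nodes.values() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}: {roots}")
        self.root: int = roots[0]
        for node in self.nodes.values():
            if node.parent_taxid not in self.nodes:
                raise TaxonomyError(
                    f"taxid {node.taxid} has parent {node.parent_taxid} "
                    "which is absent from the node table"
                )
        self._depth: dict[int, int] = {}
        for taxid in self.nodes:
            self._depth[taxid] = len(self._walk_to_root(taxid)) - 1

    def _walk_to_root(self, taxid: int) -> list[int]:
        """Parent chain from ``taxid`` up to the root (cycle-checked)."""
        chain = [taxid]
        seen = {taxid}
        current = taxid
        while current != self.root:
            current = self.nodes[current].parent_taxid
            if current in seen or len(chain) > len(self.nodes):
                raise TaxonomyError(f"cycle detected following parents of taxid {taxid}")
            seen.add(current)
            chain.append(current)
        return chain

    # -- basic queries -------------------------------------------------

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxonomyTree) and self.nodes == other.nodes

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self.nodes[taxid]
        except KeyError:
            raise TaxonomyError(f"unknown taxid {taxid}") from None

    def name(self, taxid: int) -> str:
        return self.node(taxid).scientific_name

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def depth(self, taxid: int) -> int:
        self.node(taxid)
        return self._depth[taxid]

    # -- lineage / LCA -------------------------------------------------

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from the root down to ``taxid`` (inclusive)."""
        self.node(taxid)
        return list(reversed(self._walk_to_root(taxid)))

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """The ancestor (or the node itself) carrying ``rank``, else None.

        Ranks are compared exactly after lowercasing and trimming; no
        synonym table is applied.
        """
        wanted = rank.strip().lower()
        for anc in reversed(self.lineage(taxid)):
            if self.nodes[anc].rank.strip().lower() == wanted:
                return anc
        return None

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty set of taxids.

        In a rooted tree the common ancestors of any set form a shared
        root-first prefix of the lineages; the LCA is the last element
        of that prefix.  Any set containing the root maps to the root.
        """
        ids = set(taxids)
        if not ids:
            raise TaxonomyError("lca of an empty taxid set")
        lineages = [self.lineage(t) for t in ids]
        lca = self.root
        for level in zip(*lineages):
            first = level[0]
            if all(t == first for t in level[1:]):
                lca = first
            else:
                break
        return lca

    # -- serialization -------------------------------------------------

    def write_dmp(self, nodes_handle: IO[str], names_handle: IO[str]) -> None:
        """Write the tree back in the dump dialect (round-trip safe)."""
        for taxid in sorted(self.nodes):
            node = self.nodes[taxid]
            nodes_handle.write(f"{node.taxid}\t|\t{node.parent_taxid}\t|\t{node.rank}\t|\n")
            names_handle.write(
                f"{node.taxid}\t|\t{node.scientific_name}\t|\t\t|\tscientific name\t|\n"
            )

    def write_dmp_dir(self, directory: str | Path) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes_path = directory / "nodes.dmp"
        names_path = directory / "names.dmp"
        with open(nodes_path, "wt", encoding="utf-8") as nf, open(
            names_path, "wt", encoding="utf-8"
        ) as mf:
            self.write_dmp(nf, mf)
        return nodes_path, names_path


def parse_taxonomy(
    nodes_stream: str | Path | IO[str] | Iterable[str],
    names_stream: str | Path | IO[str] | Iterable[str],
) -> TaxonomyTree:
    """Build a :class:`TaxonomyTree` from nodes/names dump streams.

    ``names_stream`` may carry several name classes per taxid (synonyms,
    common names, ...); only the record whose class is ``scientific
    name`` is used.  A taxid present in the node table but lacking a
    scientific name is an error, as is a parent taxid absent from the
    node table or a parent cycle.
    """
    raw: dict[int, tuple[int, str]] = {}
    for line in _as_lines(nodes_stream):
        if not line.strip():
            continue
        fields = _dmp_fields(line)
        if len(fields) < 3:
            raise TaxonomyError(f"nodes record has {len(fields)} fields, need >= 3: {line!r}")
        taxid, parent, rank = int(fields[0]), int(fields[1]), fields[2]
        raw[taxid] = (parent, rank)

    names: dict[int, str] = {}
    for line in _as_lines(names_stream):
        if not line.strip():
            continue
        fields = _dmp_fields(line)
        if len(fields) < 4:
            raise TaxonomyError(f"names record has {len(fields)} fields, need >= 4: {line!r}")
        taxid, name, name_class = int(fields[0]), fields[1], fields[3]
        if name_class.strip().lower() == "scientific name":
            names[taxid] = name

    nodes: dict[int, TaxonNode] = {}
    for taxid, (parent, rank) in raw.items():
        if taxid not in names:
            raise TaxonomyError(f"taxid {taxid} has no scientific name record")
        nodes[taxid] = TaxonNode(taxid, parent, rank, names[taxid])
    return TaxonomyTree(nodes)


def is_excluded_name(
    scientific_name: str,
    exclusion_terms: Iterable[str] = DEFAULT_EXCLUSION_TERMS,
) -> bool:
    """True if any exclusion term occurs in the name, case-insensitively.

    Used to skip subjects such as "uncultured bacterium" when deriving
    taxonomy from rRNA best hits.
    """
    lowered = scientific_name.lower()
    return any(term.lower() in lowered for term in exclusion_terms)
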