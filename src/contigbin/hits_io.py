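"""Reading, validating and thresholding tabular similarity-search hits.

The input is the 12-column tabular dialect produced by BLAST-style
searches (``qseqid sseqid pident length mismatch gapopen qstart qend
sstart send evalue bitscore``), optionally extended with two trailing
columns: ``nident`` (identical alignment columns) and ``staxid``
(subject taxid).  Coordinates stay 1-based inclusive as in the dialect;
reverse-strand subject matches may have s_start > s_end.

Hits are grouped per query contig and kept ordered by descending bit
score (ties: ascending E-value, then lexicographic subject accession).
E-value thresholding is strict (`evalue < threshold`), matching the
selection rule "E-value < 1e-10" for nt/nr-style databases and
"< 1e-5" for rRNA databases.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

from .taxonomy import TaxonomyTree

__all__ = [
    "AlignmentHit",
    "HitTable",
    "HitTableFormatError",
    "read_hit_table",
    "write_hit_table",
    "filter_hits",
    "resolve_taxids",
    "infer_n_ident",
    "read_acc2taxid",
]

STANDARD_COLUMNS = 12
EXTENDED_COLUMNS = 14


class HitTableFormatError(ValueError):
    """Malformed tabular hit input (message carries the line number)."""


@dataclass(frozen=True)
class AlignmentHit:
    """One similarity-search match of a contig against a reference record."""

    query_id: str
    subject_accession: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    n_ident: int | None = None
    subject_taxid: int | None = None
    unresolved: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent_identity out of [0,100]: {self.percent_identity}")
        if self.aln_length < 1:
            raise ValueError(f"aln_length must be positive: {self.aln_length}")
        if self.q_start > self.q_end:
            raise ValueError(f"q_start > q_end for query {self.query_id}")
        if self.evalue < 0:
            raise ValueError(f"negative E-value: {self.evalue}")
        if self.n_ident is not None:
            if self.n_ident > self.aln_length:
                raise ValueError(
                    f"n_ident {self.n_ident} exceeds alignment length {self.aln_length}"
                )
            implied = 100.0 * self.n_ident / self.aln_length
            if abs(self.percent_identity - implied) > 0.5:
                raise ValueError(
                    f"pident {self.percent_identity} inconsistent with "
                    f"nident {self.n_ident}/{self.aln_length} (implies {implied:.2f})"
                )


def _sort_key(hit: AlignmentHit) -> tuple:
    return (-hit.bitscore, hit.evalue, hit.subject_accession)


class HitTable:
    """Hits grouped by query contig, each group in best-hit-first order.

    Group order follows first appearance of each query id; within a
    group, hits are sorted by descending bitscore, then ascending
    E-value, then subject accession.  All mutating operations return a
    fresh table, so the ordering invariant always holds.
    """

    def __init__(self, hits: Iterable[AlignmentHit] = ()):
        groups: dict[str, list[AlignmentHit]] = {}
        for hit in hits:
            groups.setdefault(hit.query_id, []).append(hit)
        for group in groups.values():
            group.sort(key=_sort_key)
        self._groups = groups
        self.unresolved_count: int = sum(1 for h in self if h.unresolved)

    def __len__(self) -> int:
        return sum(len(g) for g in self._groups.values())

    def __iter__(self) -> Iterator[AlignmentHit]:
        for group in self._groups.values():
            yield from group

    def __eq__(self, other: object) -> bool:
        return isinstance(other, HitTable) and list(self) == list(other)

    @property
    def query_ids(self) -> list[str]:
        return list(self._groups)

    def group(self, query_id: str) -> list[AlignmentHit]:
        return list(self._groups.get(query_id, ()))

    def groups(self) -> Iterator[tuple[str, list[AlignmentHit]]]:
        for qid, group in self._groups.items():
            yield qid, list(group)


def _open_text(source: str | Path | IO[str] | Iterable[str]):
    """Open a path (gzip-transparent) or pass a handle/line iterable through."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if str(path).endswith(".gz"):
            return gzip.open(path, "rt", encoding="utf-8"), True
        return open(path, "rt", encoding="utf-8"), True
    return source, False


def _parse_row(fields: list[str], lineno: int, dialect: str) -> AlignmentHit:
    expected = {"standard": (12,), "extended": (14,), "auto": (12, 13, 14)}[dialect]
    if len(fields) not in expected:
        raise HitTableFormatError(
            f"line {lineno}: expected {' or '.join(map(str, expected))} "
            f"tab-separated columns, found {len(fields)}"
        )
    try:
        return AlignmentHit(
            query_id=fields[0],
            subject_accession=fields[1],
            percent_identity=float(fields[2]),
            aln_length=int(fields[3]),
            mismatches=int(fields[4]),
            gap_opens=int(fields[5]),
            q_start=int(fields[6]),
            q_end=int(fields[7]),
            s_start=int(fields[8]),
            s_end=int(fields[9]),
            evalue=float(fields[10]),
            bitscore=float(fields[11]),
            n_ident=int(fields[12]) if len(fields) > 12 and fields[12] != "" else None,
            subject_taxid=int(fields[13]) if len(fields) > 13 and fields[13] != "" else None,
        )
    except ValueError as exc:
        raise HitTableFormatError(f"line {lineno}: {exc}") from exc


def read_hit_table(
    source: str | Path | IO[str] | Iterable[str],
    dialect: str = "auto",
) -> HitTable:
    """Parse a tabular hit file into a :class:`HitTable`.

    ``dialect`` is ``"standard"`` (12 columns), ``"extended"``
    (14 columns: + nident, staxid) or ``"auto"`` (accept either).
    Comment lines starting with ``#`` and blank lines are skipped.
    Reading is gzip-transparent for ``.gz`` paths.
    """
    if dialect not in ("standard", "extended", "auto"):
        raise ValueError(f"unknown dialect {dialect!r}")
    handle, should_close = _open_text(source)
    hits: list[AlignmentHit] = []
    try:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.rstrip("\n")
            if not stripped.strip() or stripped.lstrip().startswith("#"):
                continue
            hits.append(_parse_row(stripped.split("\t"), lineno, dialect))
    finally:
        if should_close:
            handle.close()
    return HitTable(hits)


def _format_row(hit: AlignmentHit, dialect: str) -> str:
    base = [
        hit.query_id,
        hit.subject_accession,
        f"{hit.percent_identity:.2f}",
        str(hit.aln_length),
        str(hit.mismatches),
        str(hit.gap_opens),
        str(hit.q_start),
        str(hit.q_end),
        str(hit.s_start),
        str(hit.s_end),
        repr(hit.evalue),
        f"{hit.bitscore:.1f}",
    ]
    if dialect == "extended":
        base.append("" if hit.n_ident is None else str(hit.n_ident))
        base.append("" if hit.subject_taxid is None else str(hit.subject_taxid))
    return "\t".join(base)


def write_hit_table(
    table: HitTable,
    destination: str | Path | IO[str],
    dialect: str = "extended",
) -> None:
    """Serialize a hit table back to the tabular dialect (round-trip safe)."""
    if dialect not in ("standard", "extended"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if isinstance(destination, (str, Path)):
        handle, should_close = open(destination, "wt", encoding="utf-8"), True
    else:
        handle, should_close = destination, False
    try:
        for hit in table:
            handle.write(_format_row(hit, dialect) + "\n")
    finally:
        if should_close:
            handle.close()


def filter_hits(table: HitTable, evalue_max: float) -> HitTable:
    """Retain exactly the hits with E-value strictly below ``evalue_max``.

    A hit sitting exactly at the threshold is removed, matching the
    strict "<" selection rule.  Survivor ordering is preserved.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    return HitTable(h for h in table if h.evalue < evalue_max)


def resolve_taxids(
    table: HitTable,
    acc2taxid: Mapping[str, int],
    tree: TaxonomyTree,
) -> HitTable:
    """Fill ``subject_taxid`` from an accession map, against a taxonomy.

    A hit already carrying a taxid keeps it if the taxid exists in the
    tree.  Otherwise the accession is looked up exactly, then with its
    trailing ``.N`` version stripped.  Hits that cannot be resolved to a
    taxid present in the tree are flagged ``unresolved`` and retained;
    the returned table's ``unresolved_count`` reports how many.
    """
    resolved: list[AlignmentHit] = []
    for hit in table:
        taxid: int | None = None
        if hit.subject_taxid is not None and hit.subject_taxid in tree:
            taxid = hit.subject_taxid
        else:
            acc = hit.subject_accession
            candidate = acc2taxid.get(acc)
            if candidate is None and "." in acc:
                candidate = acc2taxid.get(acc.rsplit(".", 1)[0])
            if candidate is not None and candidate in tree:
                taxid = candidate
        if taxid is None:
            resolved.append(replace(hit, subject_taxid=None, unresolved=True))
        else:
            resolved.append(replace(hit, subject_taxid=taxid, unresolved=False))
    return HitTable(resolved)


def infer_n_ident(hit: AlignmentHit) -> int:
    """Identity count of a hit, recovered from pident when not explicit.

    Returns ``n_ident`` when present, otherwise
    ``round(percent_identity * aln_length / 100)`` with half-up
    rounding.  This is the abundance weight unit (identities per
    contig).
    """
    if hit.n_ident is not None:
        return hit.n_ident
    return int(hit.percent_identity * hit.aln_length / 100.0 + 0.5)


def read_acc2taxid(source: str | Path | IO[str] | Iterable[str]) -> dict[int, int] | dict[str, int]:
    """Read an accession->taxid TSV map.

    Accepts the 2-column toy dialect (``accession<TAB>taxid``) and the
    4-column NCBI ``accession2taxid`` dialect (``accession
    accession.version taxid gi``); a header line is skipped.  Both the
    versioned and version-stripped accession are keyed.
    """
    handle, should_close = _open_text(source)
    mapping: dict[str, int] = {}
    try:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if not line.strip() or line.startswith("#"):
                continue
            if fields[0].lower() in ("accession", "acc"):
                continue
            if len(fields) >= 3:
                acc, acc_ver, taxid = fields[0], fields[1], int(fields[2])
                mapping[acc] = taxid
                mapping[acc_ver] = taxid
            elif len(fields) == 2:
                acc, taxid = fields[0], int(fields[1])
                mapping[acc] = taxid
                if "." in acc:
                    mapping[acc.rsplit(".", 1)[0]] = taxid
            else:
                raise HitTableFormatError(
                    f"accession map line has {len(fields)} columns: {line!r}"
                )
    finally:
        if should_close:
            handle.close()
    return mapping
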