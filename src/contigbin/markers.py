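"""rRNA marker cataloging and functional-gene tabulation.

Marker contigs (e.g. 16S rRNA fragments) get their taxonomy from the
best database hit after two filters: the strict rRNA E-value cutoff and
an exclusion rule that skips subjects named like "uncultured bacterium"
or "unidentified ...", so the call always lands on a named organism.
Contigs flagged as chimeric by an external tool are dropped outright.

Functional genes (perchlorate reductase pcrABCD, chlorite dismutase
cld, nitrate reductases narG/narH/napA, ...) are annotated by resolving
hit subject accessions through NCBI-style gene2accession / gene_info
maps and an editable gene catalog, then tabulated per taxonomic group
into a counts table with an "Undefined" row for contigs whose taxonomy
does not resolve at the grouping rank, plus a totals row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .binning import Assignment
from .config import PipelineConfig
from .hits_io import AlignmentHit, HitTable, _open_text
from .taxonomy import TaxonomyTree, is_excluded_name

__all__ = [
    "MarkerRecord",
    "GeneCatalogEntry",
    "GeneAnnotation",
    "GeneMap",
    "extract_rrna_contigs",
    "load_gene_map",
    "load_gene_catalog",
    "default_gene_catalog",
    "annotate_genes",
    "tabulate_gene_taxonomy",
    "read_chimera_flags",
]

UNDEFINED_ROW = "Undefined"
TOTAL_ROW = "Total number of contigs"


@dataclass(frozen=True)
class MarkerRecord:
    """A marker-gene contig with its best admissible hit."""

    contig_id: str
    best_subject: str
    best_taxid: int
    evalue: float
    chimera_flag: bool = False


@dataclass(frozen=True)
class GeneCatalogEntry:
    """One cataloged gene: symbol, functional category, member accessions."""

    gene_symbol: str
    category: str
    member_accessions: frozenset[str] = frozenset()


@dataclass(frozen=True)
class GeneAnnotation:
    """A contig annotated with a cataloged gene via its best hit."""

    contig_id: str
    gene_symbol: str
    category: str
    hit: AlignmentHit
    source: str = "hits"


@dataclass
class GeneMap:
    """Accession -> (gene symbol, gene name) resolved from NCBI-style maps.

    ``missing_symbol_count`` tallies GeneIDs seen in gene2accession but
    absent from gene_info (their entries keep the GeneID with an empty
    symbol).
    """

    accession_to_gene: dict[str, tuple[str, str]] = field(default_factory=dict)
    missing_symbol_count: int = 0

    def lookup(self, accession: str) -> tuple[str, str] | None:
        entry = self.accession_to_gene.get(accession)
        if entry is None and "." in accession:
            entry = self.accession_to_gene.get(accession.rsplit(".", 1)[0])
        return entry


def extract_rrna_contigs(
    table: HitTable,
    tree: TaxonomyTree,
    config: PipelineConfig,
    chimera_flags: Mapping[str, bool] | None = None,
) -> list[MarkerRecord]:
    """Catalog marker contigs from an rRNA-database hit table.

    Per contig: hits are filtered at the strict rRNA E-value cutoff,
    then scanned best-first, skipping subjects whose taxon name matches
    an exclusion term (and subjects without a resolved taxid); the first
    admissible hit defines the record.  Chimera-flagged contigs are
    dropped regardless of their hits.
    """
    chimera_flags = chimera_flags or {}
    records: list[MarkerRecord] = []
    for contig_id, group in table.groups():
        if chimera_flags.get(contig_id, False):
            continue
        for hit in group:
            if hit.evalue >= config.evalue_max_rrna:
                continue
            if hit.subject_taxid is None or hit.subject_taxid not in tree:
                continue
            if is_excluded_name(tree.name(hit.subject_taxid), config.exclusion_terms):
                continue
            records.append(
                MarkerRecord(
                    contig_id=contig_id,
                    best_subject=hit.subject_accession,
                    best_taxid=hit.subject_taxid,
                    evalue=hit.evalue,
                    chimera_flag=False,
                )
            )
            break
    return records


def read_chimera_flags(source: str | Path | IO[str] | Iterable[str]) -> dict[str, bool]:
    """Read a two-column contig_id / Y-N flag file from an external tool."""
    handle, should_close = _open_text(source)
    flags: dict[str, bool] = {}
    try:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            flags[fields[0]] = fields[1].strip().upper() in ("Y", "YES", "TRUE", "1")
    finally:
        if should_close:
            handle.close()
    return flags


def load_gene_map(
    gene2accession_stream: str | Path | IO[str] | Iterable[str],
    gene_info_stream: str | Path | IO[str] | Iterable[str],
    g2a_geneid_col: int = 1,
    g2a_accession_col: int = 3,
    gi_geneid_col: int = 1,
    gi_symbol_col: int = 2,
) -> GeneMap:
    """Resolve accession -> gene from gene2accession / gene_info dialects.

    Column indices follow the NCBI layouts (gene2accession: tax_id,
    GeneID, status, RNA accession, ...; gene_info: tax_id, GeneID,
    Symbol, ...) but are configurable for trimmed fixtures.  ``-``
    placeholder accessions are skipped; both the versioned and the
    version-stripped accession are keyed.
    """
    symbols: dict[str, str] = {}
    gi_handle, close_gi = _open_text(gene_info_stream)
    try:
        for line in gi_handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= max(gi_geneid_col, gi_symbol_col):
                continue
            symbols[fields[gi_geneid_col]] = fields[gi_symbol_col]
    finally:
        if close_gi:
            gi_handle.close()

    gene_map = GeneMap()
    missing_geneids: set[str] = set()
    g2a_handle, close_g2a = _open_text(gene2accession_stream)
    try:
        for line in g2a_handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) <= max(g2a_geneid_col, g2a_accession_col):
                continue
            accession = fields[g2a_accession_col]
            if accession == "-":
                continue
            geneid = fields[g2a_geneid_col]
            symbol = symbols.get(geneid)
            if symbol is None:
                missing_geneids.add(geneid)
                entry = (geneid, "")
            else:
                entry = (symbol, symbol)
            gene_map.accession_to_gene[accession] = entry
            if "." in accession:
                gene_map.accession_to_gene[accession.rsplit(".", 1)[0]] = entry
    finally:
        if close_g2a:
            g2a_handle.close()
    gene_map.missing_symbol_count = len(missing_geneids)
    return gene_map


def load_gene_catalog(source: str | Path | IO[str] | Iterable[str]) -> list[GeneCatalogEntry]:
    """Load the editable gene catalog TSV.

    Columns: gene_symbol, category, comma-separated member accessions.
    Users extend the shipped default without code changes.
    """
    handle, should_close = _open_text(source)
    entries: list[GeneCatalogEntry] = []
    seen: set[str] = set()
    try:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"gene catalog line needs >= 2 columns: {line!r}")
            symbol, category = fields[0], fields[1]
            if symbol in seen:
                raise ValueError(f"duplicate gene symbol in catalog: {symbol}")
            seen.add(symbol)
            accs = (
                frozenset(a.strip() for a in fields[2].split(",") if a.strip())
                if len(fields) > 2
                else frozenset()
            )
            entries.append(GeneCatalogEntry(symbol, category, accs))
    finally:
        if should_close:
            handle.close()
    return entries


def default_gene_catalog() -> list[GeneCatalogEntry]:
    """The shipped catalog: perchlorate/chlorite/nitrate pathway genes."""
    from importlib.resources import files

    text = files("contigbin").joinpath("data/gene_catalog.tsv").read_text()
    return load_gene_catalog(text.splitlines())


def annotate_genes(
    table: HitTable,
    gene_map: GeneMap | None,
    catalog: Sequence[GeneCatalogEntry],
    source: str = "hits",
) -> list[GeneAnnotation]:
    """Annotate contigs with cataloged genes via their best resolving hit.

    A hit's subject resolves either through a catalog entry's member
    accessions or through the gene map to a cataloged symbol.  Scanning
    each contig's hits best-first, the first hit resolving to each
    functional category wins; a contig carries at most one annotation
    per category.
    """
    by_accession: dict[str, GeneCatalogEntry] = {}
    by_symbol: dict[str, GeneCatalogEntry] = {}
    for entry in catalog:
        by_symbol[entry.gene_symbol] = entry
        for acc in entry.member_accessions:
            by_accession[acc] = entry
            if "." in acc:
                by_accession[acc.rsplit(".", 1)[0]] = entry

    annotations: list[GeneAnnotation] = []
    for contig_id, group in table.groups():
        taken: set[str] = set()
        for hit in group:
            entry = by_accession.get(hit.subject_accession)
            if entry is None and "." in hit.subject_accession:
                entry = by_accession.get(hit.subject_accession.rsplit(".", 1)[0])
            if entry is None and gene_map is not None:
                resolved = gene_map.lookup(hit.subject_accession)
                if resolved is not None and resolved[0] in by_symbol:
                    entry = by_symbol[resolved[0]]
            if entry is None or entry.category in taken:
                continue
            taken.add(entry.category)
            annotations.append(
                GeneAnnotation(contig_id, entry.gene_symbol, entry.category, hit, source)
            )
    return annotations


def tabulate_gene_taxonomy(
    annotations: Iterable[GeneAnnotation],
    assignments: Iterable[Assignment],
    tree: TaxonomyTree,
    group_rank: str = "class",
    category: str | None = None,
) -> pd.DataFrame:
    """Count annotated contigs per taxonomic group and annotation source.

    Rows are group names at ``group_rank`` plus ``Undefined`` (contigs
    unassigned or with no ancestor at the rank); columns are the
    annotation source labels; a totals row closes the table.  When
    ``category`` is given only annotations of that category count.
    """
    assignment_by_contig = {a.contig_id: a for a in assignments}
    counts: dict[str, dict[str, int]] = {}
    sources: list[str] = []
    for ann in annotations:
        if category is not None and ann.category != category:
            continue
        if ann.source not in sources:
            sources.append(ann.source)
        assignment = assignment_by_contig.get(ann.contig_id)
        group = UNDEFINED_ROW
        if assignment is not None and assignment.assigned:
            anc = tree.ancestor_at_rank(assignment.taxid, group_rank)
            if anc is not None:
                group = tree.name(anc)
        counts.setdefault(group, {})[ann.source] = (
            counts.setdefault(group, {}).get(ann.source, 0) + 1
        )

    if not sources:
        table = pd.DataFrame(index=[UNDEFINED_ROW, TOTAL_ROW])
        table.index.name = group_rank
        return table
    named_rows = sorted(g for g in counts if g != UNDEFINED_ROW)
    named_rows.append(UNDEFINED_ROW)
    table = pd.DataFrame(
        [[counts.get(row, {}).get(src, 0) for src in sources] for row in named_rows],
        index=named_rows,
        columns=sources,
        dtype=int,
    )
    table.loc[TOTAL_ROW] = table.sum(axis=0)
    table.index.name = group_rank
    return table
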