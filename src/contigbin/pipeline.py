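"""End-to-end pipeline: hits -> binning -> profiles -> reports.

Wires the stages together over file-based inputs and writes one output
directory per community with fixed file names, so directories produced
by different runs can be compared directly:

    profile_family_ubh.tsv, profile_family_lca.tsv,
    profile_class_ubh.tsv,  profile_class_lca.tsv,
    top_families_ubh.tsv, contig_stats.tsv, markers.tsv,
    genes_<category>.tsv, manifest.json

The manifest records the config snapshot, input checksums and stage
counts so a run is auditable and reruns are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from . import binning, hits_io, markers
from .config import PipelineConfig
from .taxonomy import TaxonomyTree, parse_taxonomy

__all__ = ["HitInput", "PipelineError", "run_pipeline", "load_profile_tsv", "compare_directories"]

logger = logging.getLogger("contigbin")

PROFILE_COLUMNS = ["rank", "taxid", "name", "class_name", "weight", "proportion"]


class PipelineError(RuntimeError):
    """A missing input or inconsistent configuration at run time."""


@dataclass(frozen=True)
class HitInput:
    """One tabular hit file with its database class and label.

    ``db_class`` is ``"global"`` (nt/nr-style: strict 1e-10 cutoff,
    feeds binning and gene annotation) or ``"rrna"`` (rRNA databases:
    1e-5 cutoff, feeds the marker catalog).  The hit format does not
    carry the source database, so it is declared here.
    """

    path: Path
    db_class: str = "global"
    label: str = "hits"

    def __post_init__(self) -> None:
        if self.db_class not in ("global", "rrna"):
            raise PipelineError(f"unknown db_class {self.db_class!r}")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_profile_tsv(
    path: Path,
    profile: binning.AbundanceProfile,
    tree: TaxonomyTree,
    group_rank: str,
) -> None:
    lines = ["\t".join(PROFILE_COLUMNS) + "\n"]
    ordered = sorted(profile.entries.items(), key=lambda kv: (-kv[1][1], kv[0]))
    for taxid, (weight, prop) in ordered:
        anc = tree.ancestor_at_rank(taxid, group_rank)
        class_name = tree.name(anc) if anc is not None else "Undefined"
        lines.append(
            f"{profile.rank}\t{taxid}\t{tree.name(taxid)}\t{class_name}"
            f"\t{weight}\t{prop:.6f}\n"
        )
    lines.append(f"# unassigned_weight\t{profile.unassigned_weight}\n")
    path.write_text("".join(lines))


def load_profile_tsv(path: str | Path) -> binning.AbundanceProfile:
    """Re-read a profile TSV written by :func:`run_pipeline`."""
    path = Path(path)
    entries: dict[int, tuple[int, float]] = {}
    rank = ""
    unassigned = 0
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PROFILE_COLUMNS:
            raise PipelineError(f"{path}: unexpected profile header {header}")
        for line in fh:
            if line.startswith("# unassigned_weight"):
                unassigned = int(line.rstrip("\n").split("\t")[1])
                continue
            fields = line.rstrip("\n").split("\t")
            rank = fields[0]
            entries[int(fields[1])] = (int(fields[4]), float(fields[5]))
    return binning.AbundanceProfile(rank=rank, entries=entries, unassigned_weight=unassigned)


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        c = self.counts
        if any(v < 0 for v in c.values()):
            raise PipelineError("negative manifest count")
        if c.get("hits_retained", 0) > c.get("hits_read", 0):
            raise PipelineError("retained hits exceed hits read")
        for method in ("ubh", "lca"):
            if c.get(f"contigs_assigned_{method}", 0) > c.get("contigs_in", 0):
                raise PipelineError(f"{method} assignments exceed contig count")

    def write(self, path: Path) -> None:
        self.validate()
        path.write_text(
            json.dumps(
                {
                    "config": self.config,
                    "input_checksums": self.input_checksums,
                    "stage_seconds": self.stage_seconds,
                    "counts": self.counts,
                },
                indent=1,
                sort_keys=True,
            )
        )


def run_pipeline(
    config: PipelineConfig,
    contigs_path: str | Path,
    hit_inputs: Sequence[HitInput],
    taxonomy_dir: str | Path,
    acc2taxid_path: str | Path,
    out_dir: str | Path,
    gene2accession_path: str | Path | None = None,
    gene_info_path: str | Path | None = None,
    gene_catalog_path: str | Path | None = None,
    chimera_flags_path: str | Path | None = None,
) -> Path:
    """Run every stage over one community and write its report directory.

    Global-class hit files are E-value-filtered at the strict global
    cutoff, taxid-resolved, and assigned per contig by both UBH and
    LCA; family- and class-rank identity-weighted profiles, the
    cumulative-90% family list, and assembly statistics are written.
    rRNA-class hit files feed the marker catalog under the exclusion
    rule.  When gene maps (or the shipped catalog) are available,
    global hits are annotated and tabulated per category and class.
    """
    t0 = time.monotonic()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    required = [Path(contigs_path), Path(acc2taxid_path)] + [Path(h.path) for h in hit_inputs]
    taxonomy_dir = Path(taxonomy_dir)
    required += [taxonomy_dir / "nodes.dmp", taxonomy_dir / "names.dmp"]
    for path in required:
        if not path.exists():
            raise PipelineError(f"missing input file: {path}")

    manifest = RunManifest(config=config.to_dict())
    for path in required:
        manifest.input_checksums[str(path)] = _sha256(path)

    tree = parse_taxonomy(taxonomy_dir / "nodes.dmp", taxonomy_dir / "names.dmp")
    acc2taxid = hits_io.read_acc2taxid(Path(acc2taxid_path))
    manifest.stage_seconds["load_references"] = time.monotonic() - t0

    # Assembly statistics over the contig FASTA.
    t = time.monotonic()
    lengths = [len(rec.seq) for rec in SeqIO.parse(str(contigs_path), "fasta")]
    stats = binning.contig_stats(lengths, min_len=config.min_contig_len)
    (out_dir / "contig_stats.tsv").write_text(
        "metric\tvalue\n"
        f"n_contigs\t{stats.n_contigs}\n"
        f"total_nt\t{stats.total_nt}\n"
        f"longest\t{stats.longest}\n"
        f"shortest\t{stats.shortest}\n"
        f"mean\t{stats.mean:.1f}\n"
        f"n50\t{stats.n50}\n"
    )
    manifest.counts["contigs_in"] = len(lengths)
    manifest.stage_seconds["contig_stats"] = time.monotonic() - t

    # Global hits: filter, resolve, assign, profile.
    t = time.monotonic()
    global_hits: list[hits_io.AlignmentHit] = []
    rrna_tables: list[tuple[str, hits_io.HitTable]] = []
    hits_read = 0
    for hit_input in hit_inputs:
        table = hits_io.read_hit_table(Path(hit_input.path))
        hits_read += len(table)
        if hit_input.db_class == "global":
            filtered = hits_io.filter_hits(table, config.evalue_max_global)
            global_hits.extend(filtered)
        else:
            filtered = hits_io.filter_hits(table, config.evalue_max_rrna)
            rrna_tables.append((hit_input.label, filtered))
    global_table = hits_io.resolve_taxids(
        hits_io.HitTable(global_hits), acc2taxid, tree
    )
    manifest.counts["hits_read"] = hits_read
    manifest.counts["hits_retained"] = len(global_table) + sum(
        len(tb) for _, tb in rrna_tables
    )
    manifest.counts["hits_unresolved"] = global_table.unresolved_count
    manifest.stage_seconds["read_filter_resolve"] = time.monotonic() - t

    t = time.monotonic()
    assignments: dict[str, list[binning.Assignment]] = {"ubh": [], "lca": []}
    for contig_id, group in global_table.groups():
        assignments["ubh"].append(binning.assign_ubh(contig_id, group, tree))
        assignments["lca"].append(
            binning.assign_lca(contig_id, group, tree, config.lca_top_percent)
        )
    for method, assigned in assignments.items():
        manifest.counts[f"contigs_assigned_{method}"] = sum(
            1 for a in assigned if a.assigned
        )
        for rank_name, rank in (
            ("family", config.report_rank),
            ("class", config.group_rank),
        ):
            profile = binning.compute_profile(assigned, tree, rank)
            _write_profile_tsv(
                out_dir / f"profile_{rank_name}_{method}.tsv",
                profile,
                tree,
                config.group_rank,
            )
            if rank_name == "family":
                selected = binning.cumulative_select(profile, config.cumulative_frac)
                (out_dir / f"top_families_{method}.tsv").write_text(
                    "taxid\tname\tproportion\n"
                    + "".join(
                        f"{t_}\t{tree.name(t_)}\t{profile.proportions[t_]:.6f}\n"
                        for t_ in selected
                    )
                )
    manifest.counts["taxa_reported"] = len(
        binning.compute_profile(assignments["ubh"], tree, config.report_rank).entries
    )
    manifest.stage_seconds["binning"] = time.monotonic() - t

    # rRNA marker catalog.
    t = time.monotonic()
    chimera_flags = (
        markers.read_chimera_flags(Path(chimera_flags_path))
        if chimera_flags_path is not None
        else {}
    )
    marker_records: list[markers.MarkerRecord] = []
    for label, table in rrna_tables:
        resolved = hits_io.resolve_taxids(table, acc2taxid, tree)
        marker_records.extend(
            markers.extract_rrna_contigs(resolved, tree, config, chimera_flags)
        )
    (out_dir / "markers.tsv").write_text(
        "contig_id\tbest_subject\tbest_taxid\tbest_name\tevalue\n"
        + "".join(
            f"{m.contig_id}\t{m.best_subject}\t{m.best_taxid}"
            f"\t{tree.name(m.best_taxid)}\t{m.evalue:.3g}\n"
            for m in marker_records
        )
    )
    manifest.counts["marker_contigs"] = len(marker_records)
    manifest.stage_seconds["markers"] = time.monotonic() - t

    # Functional genes (optional inputs).
    t = time.monotonic()
    gene_map = None
    if gene2accession_path is not None and gene_info_path is not None:
        gene_map = markers.load_gene_map(Path(gene2accession_path), Path(gene_info_path))
    catalog = (
        markers.load_gene_catalog(Path(gene_catalog_path))
        if gene_catalog_path is not None
        else markers.default_gene_catalog()
    )
    annotations = markers.annotate_genes(global_table, gene_map, catalog)
    categories = sorted({e.category for e in catalog})
    for category in categories:
        table = markers.tabulate_gene_taxonomy(
            annotations, assignments["ubh"], tree, config.group_rank, category
        )
        safe = category.replace(" ", "_")
        table.to_csv(out_dir / f"genes_{safe}.tsv", sep="\t")
    manifest.counts["gene_annotations"] = len(annotations)
    manifest.stage_seconds["genes"] = time.monotonic() - t

    manifest.write(out_dir / "manifest.json")
    logger.info(
        "pipeline done: %d contigs, %d hits read, %d retained, %d UBH-assigned",
        manifest.counts["contigs_in"],
        manifest.counts["hits_read"],
        manifest.counts["hits_retained"],
        manifest.counts["contigs_assigned_ubh"],
    )
    return out_dir


def compare_directories(
    dir_a: str | Path,
    dir_b: str | Path,
    tree: TaxonomyTree | None = None,
    rank_name: str = "family",
    method: str = "ubh",
    ordering: str = "by_mean",
):
    """Compare two run directories' profiles at the same rank.

    Loads ``profile_<rank_name>_<method>.tsv`` from both directories and
    returns the comparison DataFrame (see
    :func:`contigbin.binning.compare_profiles`).
    """
    name = f"profile_{rank_name}_{method}.tsv"
    path_a, path_b = Path(dir_a) / name, Path(dir_b) / name
    for p in (path_a, path_b):
        if not p.exists():
            raise PipelineError(f"missing profile: {p}")
    profile_a = load_profile_tsv(path_a)
    profile_b = load_profile_tsv(path_b)
    return binning.compare_profiles(profile_a, profile_b, tree=tree, ordering=ordering)
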