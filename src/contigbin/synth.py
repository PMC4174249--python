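"""Synthetic community generator: taxonomy, contigs and hit tables.

Everything the pipeline consumes can be generated here with known
ground truth, so every stage is testable without any database download:

* a toy taxonomy with the fixed rank skeleton
  root > superkingdom > class > order > family > genus > species,
  written in the NCBI dump dialect;
* a two-community experiment in the style of a perchlorate-reducing
  enrichment with and without nitrate amendment: known family
  proportions, a dominant family depleted in the second community;
* contig sequences (random nucleotides) with log-normal lengths, and a
  simulated hit table per contig whose identity and bitscore decay with
  taxonomic distance from the true source taxon.

Hit model: the on-target hit covers the whole contig at around
``mean_identity`` percent identity; each off-target hit goes to a
relative, losing ``identity_decay`` percentage points of identity per
rank step to the common ancestor, and always carries a strictly lower
bitscore than the on-target hit.  Bitscore is affine in the identity
count (b = 30 + 0.18 * n_ident plus Gaussian noise) and the E-value is
the strictly monotone map E = L_q * 2**(-b); the slope keeps even the
shortest on-target hits below the 1e-10 selection threshold and the
longest contigs (capped at 3500 nt) clear of floating-point underflow.
The map is a modeling convenience, not a claim about search-statistic
biophysics — threshold logic only needs monotonicity.

All draws come from one seeded generator, consumed contig by contig, so
the first k contigs of a large community equal a k-contig community
generated with the same seed (prefix coupling, used for convergence
checks at increasing community sizes).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .taxonomy import TaxonNode, TaxonomyTree

__all__ = [
    "SyntheticCommunitySpec",
    "GroundTruth",
    "SimulationResult",
    "generate_taxonomy",
    "simulate_community",
    "make_paired_fixture",
    "default_paired_specs",
    "true_rank_proportions",
]

RANK_SKELETON = (
    "no rank",  # root
    "superkingdom",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_SYLLABLES = (
    "ba", "ce", "di", "fo", "ga", "hu", "ki", "lo", "mi", "na",
    "pe", "ra", "so", "tu", "ve", "xa", "zo", "qui", "del", "mar",
)


@dataclass(frozen=True)
class SyntheticCommunitySpec:
    """Ground-truth definition of one simulated community."""

    #: (leaf species taxid, true proportion) pairs; proportions sum to 1
    taxa: tuple[tuple[int, float], ...]
    n_contigs: int = 1000
    #: log-normal contig length model, truncated to [min_len, max_len]
    length_median: float = 230.0
    length_sigma: float = 0.55
    min_contig_len: int = 100
    max_contig_len: int = 3500
    #: mean on-target percent identity and its s.d.
    mean_identity: float = 97.0
    identity_sd: float = 1.5
    #: percentage points of identity lost per rank step from the source
    identity_decay: float = 3.0
    #: probability that a contig also gets a hit to a relative
    off_target_rate: float = 0.3
    #: bitscore model: b = intercept + slope * n_ident + N(0, noise_sd)
    bitscore_slope: float = 0.18
    bitscore_intercept: float = 30.0
    bitscore_noise_sd: float = 2.0
    seed: int = 42
    name: str = "community"

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxa proportions sum to {total}, expected 1")
        if self.n_contigs <= 0:
            raise ValueError("n_contigs must be positive")
        if self.identity_decay < 0:
            raise ValueError("identity_decay must be >= 0")


@dataclass
class GroundTruth:
    """Per-contig truth: source leaf taxid, length, on-target identities."""

    contigs: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def family_weights(self, tree: TaxonomyTree) -> dict[int, int]:
        weights: dict[int, int] = {}
        for taxid, _length, n_ident in self.contigs.values():
            fam = tree.ancestor_at_rank(taxid, "family")
            if fam is not None:
                weights[fam] = weights.get(fam, 0) + n_ident
        return weights


@dataclass
class SimulationResult:
    """Paths and truth emitted by :func:`simulate_community`."""

    spec: SyntheticCommunitySpec
    fasta_path: Path
    hits_path: Path
    acc2taxid_path: Path
    truth_path: Path
    truth: GroundTruth


def _make_name(rng: np.random.Generator, rank: str) -> str:
    k = int(rng.integers(3, 5))
    stem = "".join(_SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), k))
    suffix = {
        "class": "ia",
        "order": "ales",
        "family": "aceae",
        "genus": "us",
    }.get(rank, "")
    return (stem + suffix).capitalize()


def generate_taxonomy(
    n_families: int,
    genera_per_family: int,
    seed: int = 42,
    species_per_genus: int = 1,
    out_dir: str | Path | None = None,
) -> TaxonomyTree:
    """Build a toy taxonomy on the fixed rank skeleton.

    One superkingdom/class/order chain carries ``n_families`` families,
    each with ``genera_per_family`` genera of ``species_per_genus``
    species.  Deterministic for a seed; when ``out_dir`` is given the
    nodes/names dumps are written there and re-parse to an equal tree.
    """
    if n_families < 1 or genera_per_family < 1 or species_per_genus < 1:
        raise ValueError("taxonomy shape parameters must be >= 1")
    rng = np.random.default_rng(seed)
    nodes: dict[int, TaxonNode] = {1: TaxonNode(1, 1, "no rank", "root")}
    nodes[2] = TaxonNode(2, 1, "superkingdom", "Bacteria")
    nodes[3] = TaxonNode(3, 2, "class", _make_name(rng, "class"))
    nodes[4] = TaxonNode(4, 3, "order", _make_name(rng, "order"))
    next_id = 5
    for _ in range(n_families):
        fam_id = next_id
        nodes[fam_id] = TaxonNode(fam_id, 4, "family", _make_name(rng, "family"))
        next_id += 1
        for _ in range(genera_per_family):
            gen_id = next_id
            genus_name = _make_name(rng, "genus")
            nodes[gen_id] = TaxonNode(gen_id, fam_id, "genus", genus_name)
            next_id += 1
            for k in range(species_per_genus):
                nodes[next_id] = TaxonNode(
                    next_id, gen_id, "species", f"{genus_name} {_make_name(rng, 'species')}"
                )
                next_id += 1
    tree = TaxonomyTree(nodes)
    if out_dir is not None:
        tree.write_dmp_dir(out_dir)
    return tree


def leaf_species(tree: TaxonomyTree) -> list[int]:
    """Species-rank taxids of a tree, in taxid order."""
    return sorted(t for t, n in tree.nodes.items() if n.rank == "species")


def _accession(taxid: int) -> str:
    return f"SYN{taxid:07d}.1"


def _rank_distance(tree: TaxonomyTree, a: int, b: int) -> int:
    """Rank steps from leaf ``a`` up to the LCA with ``b``."""
    return tree.depth(a) - tree.depth(tree.lca((a, b)))


def _relatives(tree: TaxonomyTree, leaf: int, leaves: Sequence[int]) -> list[int]:
    fam = tree.ancestor_at_rank(leaf, "family")
    same_family = [
        t for t in leaves if t != leaf and tree.ancestor_at_rank(t, "family") == fam
    ]
    return same_family if same_family else [t for t in leaves if t != leaf]


def _evalue(query_len: int, bitscore: float) -> float:
    return query_len * math.pow(2.0, -bitscore)


def simulate_community(
    spec: SyntheticCommunitySpec,
    tree: TaxonomyTree,
    out_dir: str | Path,
) -> SimulationResult:
    """Emit one community's fixture set with known ground truth.

    Writes ``contigs.fasta``, an extended-dialect ``hits.tsv``, an
    ``acc2taxid.tsv`` map covering every leaf species, and
    ``truth.json``.  Deterministic for the spec's seed.  Each contig
    gets exactly one on-target hit, plus (with probability
    ``off_target_rate``) one off-target hit to a relative with decayed
    identity and strictly lower bitscore; within a contig, E-values
    strictly increase as bitscores decrease.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    leaves = leaf_species(tree)
    taxa = [t for t, _ in spec.taxa]
    props = np.array([p for _, p in spec.taxa], dtype=float)
    missing = [t for t in taxa if t not in leaves]
    if missing:
        raise ValueError(f"spec taxa are not leaf species of the tree: {missing}")

    rng = np.random.default_rng(spec.seed)
    nt = np.frombuffer(b"ACGT", dtype="S1")
    truth = GroundTruth()
    fasta_lines: list[str] = []
    hit_lines: list[str] = []

    for i in range(spec.n_contigs):
        # All randomness for one contig is drawn before the next contig
        # starts, so runs with the same seed are prefix-coupled across
        # different n_contigs.
        contig_id = f"{spec.name}_c{i + 1:06d}"
        source = taxa[int(rng.choice(len(taxa), p=props))]
        length = int(
            np.clip(
                round(float(rng.lognormal(math.log(spec.length_median), spec.length_sigma))),
                spec.min_contig_len,
                spec.max_contig_len,
            )
        )
        seq = rng.choice(nt, size=length).tobytes().decode()
        fasta_lines.append(f">{contig_id}\n{seq}\n")

        identity_on = float(
            np.clip(rng.normal(spec.mean_identity, spec.identity_sd), 50.0, 100.0)
        )
        n_ident_on = int(round(identity_on * length / 100.0))
        pident_on = round(100.0 * n_ident_on / length, 2)
        bits_on = (
            spec.bitscore_intercept
            + spec.bitscore_slope * n_ident_on
            + float(rng.normal(0.0, spec.bitscore_noise_sd))
        )
        bits_on = round(max(bits_on, 40.0), 1)
        truth.contigs[contig_id] = (source, length, n_ident_on)
        rows = [(source, pident_on, n_ident_on, bits_on)]

        off_draw = float(rng.random())
        rel_leaf = int(rng.choice(_relatives(tree, source, leaves)))
        rel_noise = float(rng.normal(0.0, spec.bitscore_noise_sd))
        if off_draw < spec.off_target_rate:
            dist = _rank_distance(tree, source, rel_leaf)
            identity_off = max(identity_on - spec.identity_decay * dist, 40.0)
            n_ident_off = int(round(identity_off * length / 100.0))
            pident_off = round(100.0 * n_ident_off / length, 2)
            bits_off = (
                spec.bitscore_intercept + spec.bitscore_slope * n_ident_off + rel_noise
            )
            # Off-target evidence never outranks the true source.
            bits_off = round(min(max(bits_off, 35.0), bits_on - 0.5), 1)
            rows.append((rel_leaf, pident_off, n_ident_off, bits_off))

        for subj, pident, n_ident, bits in rows:
            mism = length - n_ident
            hit_lines.append(
                "\t".join(
                    (
                        contig_id,
                        _accession(subj),
                        f"{pident:.2f}",
                        str(length),
                        str(mism),
                        "0",
                        "1",
                        str(length),
                        "1",
                        str(length),
                        f"{_evalue(length, bits):.6g}",
                        f"{bits:.1f}",
                        str(n_ident),
                        str(subj),
                    )
                )
                + "\n"
            )

    fasta_path = out_dir / "contigs.fasta"
    fasta_path.write_text("".join(fasta_lines))
    hits_path = out_dir / "hits.tsv"
    hits_path.write_text("".join(hit_lines))
    acc2taxid_path = out_dir / "acc2taxid.tsv"
    acc2taxid_path.write_text(
        "".join(f"{_accession(t)}\t{t}\n" for t in leaves)
    )
    truth_path = out_dir / "truth.json"
    truth_payload = {
        "name": spec.name,
        "seed": spec.seed,
        "taxa": [[t, p] for t, p in spec.taxa],
        "contigs": {
            cid: {"taxid": t, "length": l, "n_ident": n}
            for cid, (t, l, n) in truth.contigs.items()
        },
    }
    truth_path.write_text(json.dumps(truth_payload, indent=1, sort_keys=True))
    return SimulationResult(spec, fasta_path, hits_path, acc2taxid_path, truth_path, truth)


def true_rank_proportions(
    spec: SyntheticCommunitySpec, tree: TaxonomyTree, rank: str = "family"
) -> dict[int, float]:
    """Intended (specified) proportions aggregated to ``rank``."""
    out: dict[int, float] = {}
    for taxid, prop in spec.taxa:
        anc = tree.ancestor_at_rank(taxid, rank)
        if anc is not None:
            out[anc] = out.get(anc, 0.0) + prop
    return out


def make_paired_fixture(
    spec_a: SyntheticCommunitySpec,
    spec_b: SyntheticCommunitySpec,
    tree: TaxonomyTree,
    out_dir: str | Path,
) -> tuple[SimulationResult, SimulationResult]:
    """Emit both communities plus a family-level truth-difference table.

    The table (``truth_diff_family.tsv``) lists, per family, the
    intended proportions in A and B and the difference B - A, for
    checking community comparisons against construction.
    """
    out_dir = Path(out_dir)
    res_a = simulate_community(spec_a, tree, out_dir / spec_a.name)
    res_b = simulate_community(spec_b, tree, out_dir / spec_b.name)
    fams_a = true_rank_proportions(spec_a, tree)
    fams_b = true_rank_proportions(spec_b, tree)
    lines = ["family_taxid\tfamily_name\ttrue_a\ttrue_b\tdiff\n"]
    for fam in sorted(set(fams_a) | set(fams_b)):
        pa, pb = fams_a.get(fam, 0.0), fams_b.get(fam, 0.0)
        lines.append(f"{fam}\t{tree.name(fam)}\t{pa:.6f}\t{pb:.6f}\t{pb - pa:.6f}\n")
    (out_dir / "truth_diff_family.tsv").write_text("".join(lines))
    return res_a, res_b


def default_paired_specs(
    tree: TaxonomyTree,
    n_contigs: int = 5000,
    seed: int = 42,
) -> tuple[SyntheticCommunitySpec, SyntheticCommunitySpec]:
    """The shipped two-community contrast over an 8-family taxonomy.

    Community A ("perchlorate_only") is dominated by the first family;
    community B ("perchlorate_nitrate") depletes that family sharply
    and redistributes its mass — the pattern of a nitrate-amended
    enrichment losing its dominant alphaproteobacterial family.  One
    species per family carries the community (the first genus's first
    species), keeping family-level truth unambiguous.
    """
    leaves = leaf_species(tree)
    families: dict[int, int] = {}
    for leaf in leaves:
        fam = tree.ancestor_at_rank(leaf, "family")
        families.setdefault(fam, leaf)
    reps = [families[f] for f in sorted(families)]
    if len(reps) < 2:
        raise ValueError("need at least 2 families for a paired fixture")
    k = len(reps)
    props_a = np.array([0.40] + [0.60 / (k - 1)] * (k - 1))
    props_b = np.array([0.05] + [0.95 / (k - 1)] * (k - 1))
    spec_a = SyntheticCommunitySpec(
        taxa=tuple(zip(reps, (props_a / props_a.sum()).tolist())),
        n_contigs=n_contigs,
        seed=seed,
        name="perchlorate_only",
    )
    spec_b = SyntheticCommunitySpec(
        taxa=tuple(zip(reps, (props_b / props_b.sum()).tolist())),
        n_contigs=n_contigs,
        seed=seed + 1,
        name="perchlorate_nitrate",
    )
    return spec_a, spec_b
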