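"""Contig-level taxonomic binning and identity-weighted abundance.

Two assignment strategies are provided:

* **UBH** (unique best hit): a contig takes the taxon of its single
  highest-bitscore resolved hit; on a bitscore tie the LCA of the tied
  taxa is used.
* **LCA**: all resolved hits whose bitscore falls within ``top_percent``
  of the best form the candidate set, and the contig takes their lowest
  common ancestor — the conservative call when good hits disagree.

A contig's abundance weight is its identity count (the number of
identical alignment columns of its best evidence hit), so the profile
statistic at a rank is: identities in contigs assigned to a taxon,
divided by identities in contigs assigned to all taxa at that rank.
Each contig contributes exactly once; weights are never summed across a
contig's hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .hits_io import AlignmentHit, _sort_key, infer_n_ident
from .taxonomy import TaxonomyTree

__all__ = [
    "Assignment",
    "AbundanceProfile",
    "ContigStats",
    "assign_ubh",
    "assign_lca",
    "compute_profile",
    "cumulative_select",
    "compare_profiles",
    "contig_stats",
]


@dataclass(frozen=True)
class Assignment:
    """A contig's taxonomic call.  ``taxid is None`` means unassigned."""

    contig_id: str
    taxid: int | None
    method: str  # "UBH" or "LCA"
    weight: int
    evidence: tuple[AlignmentHit, ...] = ()

    def __post_init__(self) -> None:
        if (self.taxid is None) != (self.weight == 0):
            raise ValueError(
                f"{self.contig_id}: weight must be 0 exactly when unassigned"
            )
        if self.taxid is not None and not self.evidence:
            raise ValueError(f"{self.contig_id}: assigned without evidence hits")

    @property
    def assigned(self) -> bool:
        return self.taxid is not None


def _resolved_sorted(hits: Iterable[AlignmentHit], tree: TaxonomyTree) -> list[AlignmentHit]:
    """Resolved hits in canonical best-first order (input order ignored)."""
    usable = [
        h
        for h in hits
        if h.subject_taxid is not None and not h.unresolved and h.subject_taxid in tree
    ]
    usable.sort(key=_sort_key)
    return usable


def assign_ubh(
    contig_id: str,
    hits: Iterable[AlignmentHit],
    tree: TaxonomyTree,
) -> Assignment:
    """Unique-best-hit assignment for one contig's hit group.

    Hits without a resolved taxid are skipped; if every hit in the top
    bitscore stratum is unresolved the next stratum is considered.  A
    unique top hit gives its own taxon; tied top hits give their LCA,
    with the weight taken as the maximum identity count among the ties.
    """
    usable = _resolved_sorted(hits, tree)
    if not usable:
        return Assignment(contig_id, None, "UBH", 0)
    best_score = usable[0].bitscore
    tied = [h for h in usable if h.bitscore == best_score]
    if len(tied) == 1:
        taxid = tied[0].subject_taxid
    else:
        taxid = tree.lca(h.subject_taxid for h in tied)
    weight = max(infer_n_ident(h) for h in tied)
    return Assignment(contig_id, taxid, "UBH", weight, tuple(tied))


def assign_lca(
    contig_id: str,
    hits: Iterable[AlignmentHit],
    tree: TaxonomyTree,
    top_percent: float = 10.0,
) -> Assignment:
    """LCA assignment over the top-bitscore window for one contig.

    Candidates are the resolved hits with bitscore >=
    ``(1 - top_percent/100) * best``, where ``best`` is the best
    resolved bitscore.  With ``top_percent=0`` and a unique best hit
    this reduces to UBH.
    """
    if top_percent < 0:
        raise ValueError("top_percent must be >= 0")
    usable = _resolved_sorted(hits, tree)
    if not usable:
        return Assignment(contig_id, None, "LCA", 0)
    cutoff = (1.0 - top_percent / 100.0) * usable[0].bitscore
    candidates = [h for h in usable if h.bitscore >= cutoff]
    taxid = tree.lca(h.subject_taxid for h in candidates)
    weight = max(infer_n_ident(h) for h in candidates)
    return Assignment(contig_id, taxid, "LCA", weight, tuple(candidates))


@dataclass
class AbundanceProfile:
    """Identity-weighted taxon abundances at one rank.

    ``entries`` maps each taxon resolved at the rank to its total
    identity weight and its proportion of the rank-resolved total.
    Weight from contigs that are unassigned, or assigned only above the
    target rank, accumulates in ``unassigned_weight`` — reported, never
    silently dropped, and excluded from the proportion denominator.
    """

    rank: str
    entries: dict[int, tuple[int, float]]
    unassigned_weight: int = 0

    @property
    def proportions(self) -> dict[int, float]:
        return {t: p for t, (w, p) in self.entries.items()}

    @property
    def weights(self) -> dict[int, int]:
        return {t: w for t, (w, p) in self.entries.items()}

    @property
    def total_weight(self) -> int:
        return sum(w for w, _ in self.entries.values())


def compute_profile(
    assignments: Iterable[Assignment],
    tree: TaxonomyTree,
    rank: str,
) -> AbundanceProfile:
    """Aggregate assignments into an abundance profile at ``rank``.

    Each assigned contig contributes its weight to the ancestor of its
    taxon at the rank; contigs without such an ancestor (assigned above
    the rank, or unassigned) feed ``unassigned_weight``.
    """
    weights: dict[int, int] = {}
    unassigned = 0
    for a in assignments:
        if not a.assigned:
            unassigned += a.weight  # zero by invariant
            continue
        anc = tree.ancestor_at_rank(a.taxid, rank)
        if anc is None:
            unassigned += a.weight
        else:
            weights[anc] = weights.get(anc, 0) + a.weight
    total = sum(weights.values())
    entries = {
        t: (w, (w / total) if total else 0.0) for t, w in sorted(weights.items())
    }
    return AbundanceProfile(rank=rank, entries=entries, unassigned_weight=unassigned)


def cumulative_select(profile: AbundanceProfile, frac: float) -> list[int]:
    """Shortest descending-abundance prefix reaching ``frac`` cumulative.

    Entries are ordered by descending proportion (ties: ascending
    taxid); the returned prefix is minimal — dropping its last element
    would fall below ``frac``.  An empty profile yields an empty list.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must be in (0, 1]")
    ordered = sorted(profile.entries.items(), key=lambda kv: (-kv[1][1], kv[0]))
    selected: list[int] = []
    cum = 0.0
    for taxid, (_, prop) in ordered:
        selected.append(taxid)
        cum += prop
        if cum >= frac - 1e-12:
            break
    return selected


def compare_profiles(
    profile_a: AbundanceProfile,
    profile_b: AbundanceProfile,
    tree: TaxonomyTree | None = None,
    ordering: str = "by_mean",
    group_rank: str = "class",
) -> pd.DataFrame:
    """Side-by-side comparison of two same-rank abundance profiles.

    Returns one row per taxon in the union, with the proportion in each
    community (0 when absent), their mean, and the difference B - A.
    ``ordering="by_mean"`` sorts by descending mean abundance;
    ``ordering="by_class"`` groups rows by their ancestor at
    ``group_rank`` first (groups ordered by summed mean), then by mean
    within each group.  Names are filled when a taxonomy is supplied.
    """
    if profile_a.rank != profile_b.rank:
        raise ValueError(
            f"rank mismatch: {profile_a.rank!r} vs {profile_b.rank!r}"
        )
    if ordering not in ("by_mean", "by_class"):
        raise ValueError(f"unknown ordering {ordering!r}")
    taxa = sorted(set(profile_a.entries) | set(profile_b.entries))
    rows = []
    for taxid in taxa:
        pa = profile_a.proportions.get(taxid, 0.0)
        pb = profile_b.proportions.get(taxid, 0.0)
        name = tree.name(taxid) if tree is not None and taxid in tree else str(taxid)
        group = None
        if tree is not None and taxid in tree:
            anc = tree.ancestor_at_rank(taxid, group_rank)
            group = tree.name(anc) if anc is not None else None
        rows.append(
            {
                "rank": profile_a.rank,
                "taxid": taxid,
                "name": name,
                "class_name": group if group is not None else "Undefined",
                "proportion_a": pa,
                "proportion_b": pb,
                "mean": (pa + pb) / 2.0,
                "diff": pb - pa,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "rank",
            "taxid",
            "name",
            "class_name",
            "proportion_a",
            "proportion_b",
            "mean",
            "diff",
        ],
    )
    if df.empty:
        return df
    if ordering == "by_mean":
        return df.sort_values(["mean", "taxid"], ascending=[False, True]).reset_index(
            drop=True
        )
    group_mass = df.groupby("class_name")["mean"].sum()
    df["_group_mass"] = df["class_name"].map(group_mass)
    df = df.sort_values(
        ["_group_mass", "class_name", "mean", "taxid"],
        ascending=[False, True, False, True],
    ).drop(columns="_group_mass")
    return df.reset_index(drop=True)


@dataclass(frozen=True)
class ContigStats:
    """Assembly summary over retained contig lengths."""

    n_contigs: int
    total_nt: int
    longest: int
    shortest: int
    mean: float
    n50: int


def contig_stats(lengths: Sequence[int], min_len: int = 100) -> ContigStats:
    """Assembly statistics over contigs of length >= ``min_len``.

    The floor is inclusive: the assembler's stated minimum contig size
    is the shortest length it emits, so a 100 nt contig is retained
    under a 100 nt floor.  N50 is the largest length L such that
    contigs of length >= L hold at least half of the retained bases.
    """
    retained = sorted((int(l) for l in lengths if l >= min_len), reverse=True)
    if not retained:
        raise ValueError(f"no contigs of length >= {min_len}")
    total = sum(retained)
    half = total / 2.0
    cum = 0
    n50 = retained[-1]
    for length in retained:
        cum += length
        if cum >= half:
            n50 = length
            break
    return ContigStats(
        n_contigs=len(retained),
        total_nt=total,
        longest=retained[0],
        shortest=retained[-1],
        mean=total / len(retained),
        n50=n50,
    )
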