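"""Shared fixtures: toy taxonomies and hit builders."""

from __future__ import annotations

import random

import pytest

from contigbin.hits_io import AlignmentHit
from contigbin.taxonomy import TaxonNode, TaxonomyTree

# Hand-written 5-level lineage with sibling branches:
# root(1) > Bacteria(2) > Proteobacteria(3) > Rhodocyclaceae(10) > Azoarcus(11)
#                                           > Rhodocyclaceae(10) > Dechloromonas(12)
#                                           > Rhodobacteraceae(20) > Roseovarius(21)
TOY_NODES = {
    1: TaxonNode(1, 1, "no rank", "root"),
    2: TaxonNode(2, 1, "superkingdom", "Bacteria"),
    3: TaxonNode(3, 2, "class", "Proteobacteria"),
    10: TaxonNode(10, 3, "family", "Rhodocyclaceae"),
    11: TaxonNode(11, 10, "genus", "Azoarcus"),
    12: TaxonNode(12, 10, "genus", "Dechloromonas"),
    20: TaxonNode(20, 3, "family", "Rhodobacteraceae"),
    21: TaxonNode(21, 20, "genus", "Roseovarius"),
}


@pytest.fixture
def toy_tree() -> TaxonomyTree:
    return TaxonomyTree(TOY_NODES)


def random_tree(n_nodes: int, seed: int) -> TaxonomyTree:
    """Random rooted tree: each new node picks a uniform existing parent."""
    rng = random.Random(seed)
    ranks = ["no rank", "class", "order", "family", "genus", "species"]
    nodes = {1: TaxonNode(1, 1, "no rank", "root")}
    for taxid in range(2, n_nodes + 1):
        parent = rng.choice(list(nodes))
        nodes[taxid] = TaxonNode(taxid, parent, rng.choice(ranks), f"taxon{taxid}")
    return TaxonomyTree(nodes)


def brute_force_lca(tree: TaxonomyTree, taxids) -> int:
    """Independent LCA oracle: deepest member of the ancestor-set intersection."""
    common = None
    for taxid in taxids:
        ancestors = set(tree.lineage(taxid))
        common = ancestors if common is None else (common & ancestors)
    return max(common, key=tree.depth)


def make_hit(
    query="c1",
    subject="ACC00001.1",
    pident=95.0,
    length=100,
    evalue=1e-30,
    bitscore=100.0,
    n_ident=None,
    taxid=None,
) -> AlignmentHit:
    mism = length - (n_ident if n_ident is not None else round(pident * length / 100))
    return AlignmentHit(
        query_id=query,
        subject_accession=subject,
        percent_identity=pident,
        aln_length=length,
        mismatches=mism,
        gap_opens=0,
        q_start=1,
        q_end=length,
        s_start=1,
        s_end=length,
        evalue=evalue,
        bitscore=bitscore,
        n_ident=n_ident,
        subject_taxid=taxid,
    )
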