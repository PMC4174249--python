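"""Marker cataloging, gene annotation/tabulation and alignment identity."""

import io
import itertools
import random

import pytest

from contigbin.align import AlphabetError, global_percent_identity
from contigbin.binning import Assignment
from contigbin.config import PipelineConfig
from contigbin.hits_io import HitTable
from contigbin.markers import (
    GeneCatalogEntry,
    TOTAL_ROW,
    UNDEFINED_ROW,
    annotate_genes,
    default_gene_catalog,
    extract_rrna_contigs,
    load_gene_map,
    tabulate_gene_taxonomy,
)

from conftest import make_hit


@pytest.fixture
def excl_tree(toy_tree):
    # add an "uncultured bacterium" leaf under the class
    from contigbin.taxonomy import TaxonNode, TaxonomyTree

    nodes = dict(toy_tree.nodes)
    nodes[30] = TaxonNode(30, 3, "species", "uncultured bacterium")
    return TaxonomyTree(nodes)


class TestExtractRRNA:
    def test_excluded_best_hit_falls_to_next(self, excl_tree):
        table = HitTable(
            [
                make_hit(subject="UNC.1", taxid=30, bitscore=120, evalue=1e-20),
                make_hit(subject="ROS.1", taxid=21, bitscore=100, evalue=1e-15),
            ]
        )
        records = extract_rrna_contigs(table, excl_tree, PipelineConfig())
        assert len(records) == 1
        assert records[0].best_taxid == 21  # the named organism wins

    def test_rrna_threshold_is_strict(self, excl_tree):
        table = HitTable([make_hit(evalue=1e-4, taxid=21)])
        assert extract_rrna_contigs(table, excl_tree, PipelineConfig()) == []
        at = HitTable([make_hit(evalue=1e-5, taxid=21)])
        assert extract_rrna_contigs(at, excl_tree, PipelineConfig()) == []

    def test_chimera_flag_drops_contig(self, excl_tree):
        table = HitTable([make_hit(query="chi1", taxid=21, evalue=1e-20)])
        records = extract_rrna_contigs(
            table, excl_tree, PipelineConfig(), chimera_flags={"chi1": True}
        )
        assert records == []

    def test_output_subset_of_queries(self, excl_tree):
        rng = random.Random(14)
        hits = [
            make_hit(query=f"c{i%10}", subject=f"S{i}.1", taxid=rng.choice([21, 30, None]),
                     evalue=10.0 ** -rng.uniform(2, 20))
            for i in range(60)
        ]
        table = HitTable(hits)
        records = extract_rrna_contigs(table, excl_tree, PipelineConfig())
        assert {r.contig_id for r in records} <= set(table.query_ids)
        for r in records:
            assert r.evalue < PipelineConfig().evalue_max_rrna
            assert not excl_tree.name(r.best_taxid).startswith("uncultured")


G2A = (
    "#tax_id\tGeneID\tstatus\tnucl_accession\n"
    "222\t5001\tVALIDATED\tSYNPCRA01.1\n"
    "222\t5001\tVALIDATED\tSYNPCRA02.1\n"
    "222\t5002\tVALIDATED\tSYNCLD01.1\n"
    "222\t5003\tVALIDATED\t-\n"
    "222\t5004\tVALIDATED\tSYNNARG01.1\n"
)
GENE_INFO = (
    "#tax_id\tGeneID\tSymbol\n"
    "222\t5001\tpcrA\n"
    "222\t5002\tcld\n"
    "222\t5004\tnarG\n"
)


class TestGeneMap:
    def test_basic_and_version_stripped(self):
        gm = load_gene_map(io.StringIO(G2A), io.StringIO(GENE_INFO))
        assert gm.lookup("SYNPCRA01.1")[0] == "pcrA"
        assert gm.lookup("SYNPCRA01")[0] == "pcrA"

    def test_shared_geneid_maps_both_accessions(self):
        gm = load_gene_map(io.StringIO(G2A), io.StringIO(GENE_INFO))
        assert gm.lookup("SYNPCRA02.1")[0] == "pcrA"

    def test_dash_accession_skipped(self):
        gm = load_gene_map(io.StringIO(G2A), io.StringIO(GENE_INFO))
        assert gm.lookup("-") is None

    def test_missing_geneid_keeps_id_and_counts(self):
        g2a = "222\t9999\tVALIDATED\tSYNX01.1\n"
        gm = load_gene_map(io.StringIO(g2a), io.StringIO(GENE_INFO))
        assert gm.lookup("SYNX01.1") == ("9999", "")
        assert gm.missing_symbol_count == 1


CATALOG = [
    GeneCatalogEntry("pcrA", "perchlorate reduction", frozenset({"SYNPCRA01"})),
    GeneCatalogEntry("cld", "chlorite dismutation", frozenset({"SYNCLD01"})),
    GeneCatalogEntry("narG", "nitrate reduction", frozenset({"SYNNARG01"})),
]


class TestAnnotate:
    def test_member_accession_resolves(self):
        table = HitTable([make_hit(query="c1", subject="SYNCLD01.1")])
        anns = annotate_genes(table, None, CATALOG)
        assert [(a.gene_symbol, a.category) for a in anns] == [
            ("cld", "chlorite dismutation")
        ]

    def test_uncataloged_subject_unannotated(self):
        table = HitTable([make_hit(query="c1", subject="OTHER.1")])
        assert annotate_genes(table, None, CATALOG) == []

    def test_best_hit_wins_within_category(self):
        table = HitTable(
            [
                make_hit(query="c1", subject="SYNNARG01.1", bitscore=80),
                make_hit(query="c1", subject="SYNPCRA01.1", bitscore=95),
            ]
        )
        anns = annotate_genes(table, None, CATALOG)
        by_cat = {a.category: a.gene_symbol for a in anns}
        assert by_cat["perchlorate reduction"] == "pcrA"
        assert by_cat["nitrate reduction"] == "narG"

    def test_gene_map_route(self):
        gm = load_gene_map(io.StringIO(G2A), io.StringIO(GENE_INFO))
        table = HitTable([make_hit(query="c1", subject="SYNPCRA02.1")])
        anns = annotate_genes(table, gm, CATALOG)
        assert anns[0].gene_symbol == "pcrA"

    def test_idempotent(self):
        table = HitTable(
            [make_hit(query=f"c{i}", subject="SYNCLD01.1") for i in range(5)]
        )
        first = annotate_genes(table, None, CATALOG)
        second = annotate_genes(table, None, CATALOG)
        assert first == second

    def test_default_catalog_ships_expected_genes(self):
        symbols = {e.gene_symbol for e in default_gene_catalog()}
        assert {"pcrA", "pcrB", "pcrC", "pcrD", "cld", "narG", "narH", "napA"} <= symbols


class TestTabulate:
    def _annotations(self, contigs):
        return [
            a
            for cid in contigs
            for a in annotate_genes(
                HitTable([make_hit(query=cid, subject="SYNNARG01.1")]), None, CATALOG
            )
        ]

    def test_counting_example(self, toy_tree):
        anns = self._annotations(["c1", "c2", "c3"])
        assignments = [
            Assignment("c1", 11, "UBH", 10, (make_hit(),)),
            Assignment("c2", 12, "UBH", 10, (make_hit(),)),
            Assignment("c3", None, "UBH", 0),
        ]
        table = tabulate_gene_taxonomy(anns, assignments, toy_tree, "class")
        assert table.loc["Proteobacteria", "hits"] == 2
        assert table.loc[UNDEFINED_ROW, "hits"] == 1
        assert table.loc[TOTAL_ROW, "hits"] == 3

    def test_empty_annotations_zero_totals(self, toy_tree):
        table = tabulate_gene_taxonomy([], [], toy_tree, "class")
        assert TOTAL_ROW in table.index
        assert table.loc[TOTAL_ROW].sum() == 0 if len(table.columns) else True

    def test_totals_row_equals_column_sums_fuzzed(self, toy_tree):
        rng = random.Random(31)
        for _ in range(25):
            n = rng.randint(1, 40)
            contigs = [f"c{i}" for i in range(n)]
            anns = self._annotations(contigs)
            assignments = [
                Assignment(cid, rng.choice([11, 12, 21, 1]), "UBH", 10, (make_hit(),))
                if rng.random() < 0.8
                else Assignment(cid, None, "UBH", 0)
                for cid in contigs
            ]
            table = tabulate_gene_taxonomy(anns, assignments, toy_tree, "class")
            body = table.drop(index=TOTAL_ROW)
            assert (table.loc[TOTAL_ROW] == body.sum(axis=0)).all()
            assert int(table.loc[TOTAL_ROW].sum()) == len(anns)
            # Undefined row absorbs exactly the rank-unresolved contigs
            unresolved = sum(
                1
                for a in assignments
                if not a.assigned or toy_tree.ancestor_at_rank(a.taxid, "class") is None
            )
            assert int(body.loc[UNDEFINED_ROW].sum()) == unresolved


def enumerate_alignments(a, b):
    """Yield (moves, score, ident) for every global alignment (match +1,
    mismatch -1, gap -2); independent brute-force oracle."""
    def rec(i, j, moves, score, ident):
        if i == len(a) and j == len(b):
            yield tuple(moves), score, ident
            return
        if i < len(a) and j < len(b):
            same = a[i] == b[j]
            moves.append("d")
            yield from rec(i + 1, j + 1, moves, score + (1 if same else -1), ident + same)
            moves.pop()
        if i < len(a):
            moves.append("u")
            yield from rec(i + 1, j, moves, score - 2, ident)
            moves.pop()
        if j < len(b):
            moves.append("l")
            yield from rec(i, j + 1, moves, score - 2, ident)
            moves.pop()

    yield from rec(0, 0, [], 0, 0)


def oracle_identity(a, b):
    """Identity of the optimal alignment the deterministic traceback picks:
    among optimal-score alignments, the one whose end-to-start move
    sequence is lexicographically smallest under d < u < l."""
    order = {"d": 0, "u": 1, "l": 2}
    best = None
    for moves, score, ident in enumerate_alignments(a, b):
        key = tuple(order[m] for m in reversed(moves))
        cand = (-score, key, ident)
        if best is None or cand[:2] < best[:2]:
            best = cand
    return 100.0 * best[2] / len(best[1])


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_percent_identity("ACGTACGT", "ACGTACGT") == 100.0

    def test_hand_traced_example(self):
        # ACGT vs ACGA aligns without gaps: 3 of 4 columns identical.
        assert global_percent_identity("ACGT", "ACGA") == 75.0

    def test_matches_enumeration_oracle(self):
        rng = random.Random(17)
        for _ in range(60):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 7)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 7)))
            assert global_percent_identity(a, b) == pytest.approx(oracle_identity(a, b))

    def test_symmetric_for_symmetric_scoring(self):
        rng = random.Random(23)
        for _ in range(30):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            assert global_percent_identity(a, b) == pytest.approx(
                global_percent_identity(b, a)
            )

    def test_score_agrees_with_biopython_aligner(self):
        # independent cross-check that the DP reaches the optimal score
        from Bio import Align

        from contigbin.align import global_alignment_score

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        rng = random.Random(29)
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(2, 12)))
            assert global_alignment_score(a, b) == aligner.score(a, b)

    def test_protein_mode(self):
        assert global_percent_identity("MKV", "MKV", matrix_name="BLOSUM62") == 100.0

    def test_alphabet_mismatch_errors(self):
        with pytest.raises(AlphabetError):
            global_percent_identity("ACGT", "MKVLW")

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            global_percent_identity("", "ACGT")
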