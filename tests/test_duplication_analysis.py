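import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgascape.duplication_analysis import (
    DuplicatePair,
    call_duplicates,
    call_paralogs,
    duplication_summary,
    label_tandem_clusters,
    paralog_groups,
    type_pair,
    type_pairs,
)
from rgascape.genome_landscape import GeneCluster
from rgascape.io_formats import make_hit

from conftest import make_gene


def hit(q, s, identity=85.0, qcov=95.0, scov=95.0, evalue=1e-50, bits=200.0):
    return make_hit(
        q, s, identity, 95, evalue, bits, 100, 100,
        query_span=int(qcov), subject_span=int(scov),
    )


class TestCallDuplicates:
    def test_passing_hit_retained(self, cfg):
        pairs = call_duplicates([hit("a", "b", 71.0, 75.0, 80.0)], cfg)
        assert [p.key for p in pairs] == [("a", "b")]

    def test_identity_below_threshold_rejected(self, cfg):
        assert call_duplicates([hit("a", "b", 69.9, 99.0, 99.0)], cfg) == []

    def test_coverage_on_both_sides_required(self, cfg):
        assert call_duplicates([hit("a", "b", 90.0, 99.0, 50.0)], cfg) == []

    def test_reciprocal_hits_collapse_keeping_best(self, cfg):
        h1 = hit("a", "b", 80.0, evalue=1e-40, bits=150.0)
        h2 = hit("b", "a", 85.0, evalue=1e-60, bits=250.0)
        (pair,) = call_duplicates([h1, h2], cfg)
        assert pair.evidence is h2

    def test_self_hits_ignored(self, cfg):
        assert call_duplicates([hit("a", "a")], cfg) == []


class TestTypePair:
    @pytest.fixture
    def positions(self):
        return {
            "a1": make_gene("a1", "A01", 1_000_000),
            "a2": make_gene("a2", "A01", 5_200_000),
            "b1": make_gene("b1", "B03", 1_000_000),
            "b2": make_gene("b2", "B03", 7_100_000),
            "b5": make_gene("b5", "B05", 2_000_000),
        }

    def test_within_tandem_distance(self, cfg, positions):
        pair = DuplicatePair("a1", "a2")
        assert type_pair(pair, positions, cfg) == ("TANDEM", "INTRA_A")

    def test_beyond_tandem_distance_segmental(self, cfg, positions):
        pair = DuplicatePair("b1", "b2")
        assert type_pair(pair, positions, cfg) == ("SEGMENTAL", "INTRA_B")

    def test_cross_subgenome_dispersed_inter(self, cfg, positions):
        pair = DuplicatePair("a1", "b5")
        assert type_pair(pair, positions, cfg) == ("DISPERSED", "INTER")

    def test_unplaced_gene_is_dispersed(self, cfg, positions):
        positions["u1"] = make_gene("u1", "UNPLACED", 1, sub_genome="NONE")
        pair = DuplicatePair("a1", "u1")
        ptype, scope = type_pair(pair, positions, cfg)
        assert ptype == "DISPERSED"
        assert scope == "OTHER"

    def test_exact_5mb_is_tandem(self, cfg):
        positions = {
            "x": make_gene("x", "A02", 1),
            "y": make_gene("y", "A02", 5_000_001),
        }
        assert type_pair(DuplicatePair("x", "y"), positions, cfg)[0] == "TANDEM"


class TestDuplicationSummary:
    def test_gene_and_event_counts(self):
        pairs = [DuplicatePair("a", "b"), DuplicatePair("b", "c")]
        s = duplication_summary(pairs, 10)
        assert s.n_duplicated_genes == 3
        assert s.n_events == 2

    def test_scope_partition(self, paper_bundle):
        for family, expected in (
            ("RLK", {"INTRA_A": 83, "INTRA_B": 80, "INTER": 308, "OTHER": 0}),
            ("RLP", {"INTRA_A": 20, "INTRA_B": 32, "INTER": 58, "OTHER": 0}),
        ):
            s = paper_bundle.species["tetraploid"].dup_summary[family]
            assert s.events_by_scope == expected
            assert sum(s.events_by_scope.values()) == s.n_events

    def test_paper_fixture_headline_counts(self, paper_bundle):
        rlk = paper_bundle.species["tetraploid"].dup_summary["RLK"]
        assert (rlk.n_events, rlk.n_duplicated_genes) == (471, 413)
        rlp = paper_bundle.species["tetraploid"].dup_summary["RLP"]
        assert (rlp.n_events, rlp.n_duplicated_genes) == (110, 112)


class TestCallParalogs:
    def test_passing_evalue_distinct_loci(self, cfg):
        positions = {"a": make_gene("a", "A01", 1), "b": make_gene("b", "A02", 1)}
        pairs = call_paralogs([hit("a", "b", evalue=1e-25)], cfg, positions)
        assert pairs == {("a", "b")}

    def test_failing_evalue(self, cfg):
        assert call_paralogs([hit("a", "b", evalue=1e-15)], cfg) == set()

    def test_identity_not_required(self, cfg):
        # the paralog rule is E-value only, unlike the duplicate rule
        pairs = call_paralogs([hit("a", "b", identity=50.0, evalue=1e-25)], cfg)
        assert pairs == {("a", "b")}

    def test_colocated_records_rejected(self, cfg):
        positions = {"a": make_gene("a", "A01", 100), "b": make_gene("b", "A01", 100)}
        assert call_paralogs([hit("a", "b", evalue=1e-30)], cfg, positions) == set()

    def test_group_of_three(self, cfg):
        hits = [
            hit("k1", "k2", evalue=1e-30),
            hit("k2", "k3", evalue=1e-30),
            hit("k1", "k3", evalue=1e-30),
        ]
        pairs = call_paralogs(hits, cfg)
        groups = paralog_groups(pairs)
        assert groups == [{"k1", "k2", "k3"}]


class TestLabelTandemClusters:
    def _cluster(self):
        return GeneCluster("c", "A01", ["a", "b", "c"], 50_000)

    def test_all_consecutive_tandem(self):
        pairs = [
            DuplicatePair("a", "b", positional_type="TANDEM"),
            DuplicatePair("b", "c", positional_type="TANDEM"),
        ]
        (c,) = label_tandem_clusters([self._cluster()], pairs)
        assert c.tandem

    def test_one_missing_link_breaks_tandem(self):
        pairs = [DuplicatePair("a", "b", positional_type="TANDEM")]
        (c,) = label_tandem_clusters([self._cluster()], pairs)
        assert not c.tandem

    def test_paper_fixture_tandem_cluster_shares(self, paper_bundle):
        clusters = paper_bundle.species["tetraploid"].clusters
        assert sum(1 for c in clusters["RLK"] if c.tandem) == 6
        assert len(clusters["RLK"]) == 16
        assert sum(1 for c in clusters["RLP"] if c.tandem) == 6
        assert len(clusters["RLP"]) == 7


# --- symmetry / dedup property and brute-force recount oracle ---------------


@settings(max_examples=40, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.integers(0, 9),
            st.integers(0, 9),
            st.floats(50, 100),
            st.booleans(),
        ),
        max_size=30,
    )
)
def test_calls_symmetric_and_deduplicated(raw):
    cfg_ = __import__("rgascape.io_formats", fromlist=["AnalysisConfig"]).AnalysisConfig()
    hits = [
        hit(f"g{q}", f"g{s}", identity, 95.0, 95.0)
        for q, s, identity, _swap in raw
    ]
    swapped = [
        hit(f"g{s}" if swap else f"g{q}", f"g{q}" if swap else f"g{s}", identity, 95.0, 95.0)
        for q, s, identity, swap in raw
    ]
    random.Random(3).shuffle(swapped)
    keys = lambda hs: [p.key for p in call_duplicates(hs, cfg_)]
    assert keys(hits) == keys(swapped)


@settings(max_examples=40, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 19), st.integers(0, 19), st.sampled_from(
            ["TANDEM", "SEGMENTAL", "DISPERSED"]
        ), st.sampled_from(["INTRA_A", "INTRA_B", "INTER"])),
        max_size=25,
    )
)
def test_summary_matches_bruteforce_recount(raw):
    pairs = {}
    for a, b, ptype, scope in raw:
        if a == b:
            continue
        key = tuple(sorted((f"g{a}", f"g{b}")))
        pairs[key] = DuplicatePair(*key, positional_type=ptype, genome_scope=scope)
    pair_list = list(pairs.values())
    s = duplication_summary(pair_list, 20)

    genes = set()
    tandem, seg = set(), set()
    scopes = {"INTRA_A": 0, "INTRA_B": 0, "INTER": 0, "OTHER": 0}
    for p in pair_list:
        genes |= {p.gene_a, p.gene_b}
        if p.positional_type == "TANDEM":
            tandem |= {p.gene_a, p.gene_b}
        if p.positional_type == "SEGMENTAL":
            seg |= {p.gene_a, p.gene_b}
        scopes[p.genome_scope] += 1
    assert s.n_duplicated_genes == len(genes)
    assert s.n_tandem_genes == len(tandem)
    assert s.n_segmental_genes == len(seg)
    assert s.events_by_scope == scopes
    assert s.n_events == len(pair_list)


def test_same_chromosome_pairs_are_exactly_tandem_or_segmental(sim_world, sim_bundle, cfg):
    positions = sim_world.positions()
    for family in ("RLK", "RLP"):
        for p in sim_bundle.species["tetraploid"].duplicate_pairs[family]:
            same_chrom = (
                positions[p.gene_a].placed
                and positions[p.gene_b].placed
                and positions[p.gene_a].chromosome == positions[p.gene_b].chromosome
            )
            assert same_chrom == (p.positional_type in ("TANDEM", "SEGMENTAL"))


def test_noiseless_recovery_precision_recall_one(sim_world, sim_bundle):
    gt = sim_world.ground_truth
    for family in ("RLK", "RLP"):
        recovered = {p.key for p in sim_bundle.species["tetraploid"].duplicate_pairs[family]}
        planted = set(gt.pairs[("tetraploid", family)])
        assert recovered == planted
        for p in sim_bundle.species["tetraploid"].duplicate_pairs[family]:
            assert (p.positional_type, p.genome_scope) == gt.pairs[
                ("tetraploid", family)
            ][p.key]
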