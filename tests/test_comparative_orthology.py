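import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgascape.comparative_orthology import (
    OrthologPair,
    _lis_anchor_indices,
    call_orthologs,
    compare_family_sizes,
    conservation_ledger,
    synteny_chains,
)
from rgascape.io_formats import AnalysisConfig, make_hit

from conftest import make_gene


def xhit(q, s, identity=85.0, cov=95.0, evalue=1e-50):
    span = int(cov)
    return make_hit(q, s, identity, span, evalue, 200.0, 100, 100, span, span)


class TestCallOrthologs:
    def test_passing_hit(self, cfg):
        (op,) = call_orthologs([xhit("t1", "p1", 85.0, 90.0, 1e-50)], cfg)
        assert (op.gene_tetraploid, op.gene_progenitor) == ("t1", "p1")

    def test_evalue_rule_is_strict(self, cfg):
        assert call_orthologs([xhit("t1", "p1", 95.0, 99.0, 1e-40)], cfg) == []

    def test_similarity_threshold(self, cfg):
        assert call_orthologs([xhit("t1", "p1", 69.0, 99.0, 1e-60)], cfg) == []

    def test_within_species_hit_never_ortholog(self, cfg):
        hits = [xhit("t1", "t2", 95.0, 99.0, 1e-60)]
        assert call_orthologs(hits, cfg, tetraploid_ids={"t1", "t2"}) == []

    def test_symmetric_in_species_order(self, cfg):
        fwd = call_orthologs([xhit("t1", "p1")], cfg, tetraploid_ids={"t1"})
        rev = call_orthologs([xhit("p1", "t1")], cfg, tetraploid_ids={"t1"})
        assert [(o.gene_tetraploid, o.gene_progenitor) for o in fwd] == [
            (o.gene_tetraploid, o.gene_progenitor) for o in rev
        ]

    def test_bbh_switch_requires_both_directions(self):
        cfg = AnalysisConfig(bbh=True)
        one_way = call_orthologs([xhit("t1", "p1")], cfg, tetraploid_ids={"t1"})
        assert one_way == []
        both = call_orthologs(
            [xhit("t1", "p1"), xhit("p1", "t1")], cfg, tetraploid_ids={"t1"}
        )
        assert len(both) == 1

    def test_many_to_many_permitted(self, cfg):
        hits = [xhit("t1", "p1"), xhit("t1", "p2"), xhit("t2", "p1")]
        assert len(call_orthologs(hits, cfg)) == 3


def ortholog(t, p):
    return OrthologPair(t, p, xhit(t, p))


class TestConservationLedger:
    def test_paper_a_subgenome_counts(self):
        tet = [make_gene(f"t{i}", "A01", 1 + 500_000 * i) for i in range(236)]
        prog = [
            make_gene(f"p{i}", "A01", 1 + 500_000 * i, species="prog")
            for i in range(300)
        ]
        orthologs = [ortholog(f"t{i}", f"p{i}") for i in range(194)]
        s = conservation_ledger(tet, prog, orthologs, "A", "prog", "RLK")
        assert s.tetraploid_conserved == 194
        assert s.gained == 42
        assert s.progenitor_conserved == 194
        assert s.lost == 106

    def test_no_orthologs_all_gained(self):
        tet = [make_gene("t1"), make_gene("t2", start=900_000)]
        s = conservation_ledger(tet, [], [], "A", "prog")
        assert s.tetraploid_conserved == 0
        assert s.gained == s.tetraploid_total == 2

    def test_progenitor_losses(self):
        prog = [
            make_gene(f"p{i}", "B01", 1 + 500_000 * i, species="prog")
            for i in range(176)
        ]
        tet = [make_gene(f"t{i}", "B02", 1 + 500_000 * i) for i in range(117)]
        orthologs = [ortholog(f"t{i}", f"p{i}") for i in range(72)]
        s = conservation_ledger(tet, prog, orthologs, "B", "prog", "RLP")
        assert s.progenitor_conserved == 72
        assert s.lost == 104

    def test_unknown_species_is_hard_error(self):
        prog = [make_gene("p1", species="other")]
        with pytest.raises(ValueError, match="prog"):
            conservation_ledger([], prog, [], "A", "prog")

    def test_ledger_closure_on_paper_fixture(self, paper_bundle):
        for s in paper_bundle.conservation:
            assert s.tetraploid_conserved + s.gained == s.tetraploid_total
            assert s.progenitor_conserved + s.lost == s.progenitor_total

    def test_paper_fixture_conserved_counts(self, paper_bundle):
        by_key = {(s.family, s.sub_genome): s for s in paper_bundle.conservation}
        assert by_key[("RLK", "A")].tetraploid_conserved == 194
        assert by_key[("RLK", "B")].tetraploid_conserved == 189
        assert by_key[("RLP", "A")].tetraploid_conserved == 24
        assert by_key[("RLP", "B")].tetraploid_conserved == 65
        assert by_key[("RLK", "A")].gained == 42
        assert by_key[("RLK", "A")].lost == 86
        assert by_key[("RLP", "B")].lost == 104


def _anchor_world(prog_positions, chrom="A03"):
    """Tetraploid genes in order 0..n-1 on one chromosome; progenitor genes at
    the given start positions on the same-named chromosome."""
    positions = {}
    orthologs = []
    for i, p in enumerate(prog_positions):
        t, pr = f"t{i}", f"p{i}"
        positions[t] = make_gene(t, chrom, 1_000_000 * (i + 1))
        positions[pr] = make_gene(pr, chrom, p, species="prog")
        orthologs.append(ortholog(t, pr))
    return orthologs, positions


class TestSyntenyChains:
    def test_collinear_anchors_form_one_chain(self, cfg):
        orthologs, positions = _anchor_world([100, 200, 300, 400])
        chains, syntenic = synteny_chains(orthologs, positions, cfg)
        assert len(chains) == 1
        assert chains[0].length == 4
        assert syntenic == {"t0", "t1", "t2", "t3"}

    def test_short_increasing_subsequence_reports_nothing(self, cfg):
        orthologs, positions = _anchor_world([300, 100, 200])
        chains, syntenic = synteny_chains(orthologs, positions, cfg)
        assert chains == [] and syntenic == set()

    def test_displaced_inverted_block_excluded(self, cfg):
        # 20 anchors; a 5-anchor block is inverted and displaced beyond the
        # rest: the chain keeps the other 15 anchors only
        values = list(range(1, 8)) + [104, 103, 102, 101, 100] + list(range(8, 16))
        orthologs, positions = _anchor_world([v * 1000 for v in values])
        chains, syntenic = synteny_chains(orthologs, positions, cfg)
        assert len(chains) == 1
        assert chains[0].length == 15
        assert syntenic == {f"t{i}" for i in range(20) if not 7 <= i <= 11}

    def test_unplaced_progenitor_excluded(self, cfg):
        positions = {
            "t0": make_gene("t0", "A01", 100),
            "p0": make_gene("p0", "UNPLACED", 1, species="prog", sub_genome="NONE"),
        }
        chains, syntenic = synteny_chains([ortholog("t0", "p0")], positions, cfg)
        assert chains == [] and syntenic == set()

    def test_paper_fixture_syntenic_count(self, paper_world, paper_bundle):
        chains, syntenic = paper_bundle.synteny[("RLK", "A")]
        assert len(syntenic) == 192
        assert syntenic == paper_world.ground_truth.syntenic[("RLK", "A")]
        assert paper_bundle.synteny[("RLK", "B")][1] == set()


# --- LIS oracle: brute force over all subsequences (<=15 anchors) -----------


def brute_force_lis(seq):
    best = 0
    for r in range(len(seq), 0, -1):
        for combo in itertools.combinations(range(len(seq)), r):
            vals = [seq[i] for i in combo]
            if all(x < y for x, y in zip(vals, vals[1:])):
                return r
    return best


@settings(max_examples=60, deadline=None)
@given(st.lists(st.integers(0, 100), min_size=0, max_size=12, unique=True))
def test_lis_matches_bruteforce(seq):
    t_pos = list(range(len(seq)))
    chain = _lis_anchor_indices(t_pos, seq)
    vals = [seq[i] for i in chain]
    assert all(x < y for x, y in zip(vals, vals[1:]))
    assert len(chain) == brute_force_lis(seq)


class TestCompareFamilySizes:
    def test_counts_per_species(self):
        table = compare_family_sizes(
            {
                "sp1": {"g1": "LRR_RLK", "g2": "NON_RGA", "g3": "LRR_RLP"},
                "sp2": {"h1": "LYSM_RLK"},
            }
        )
        assert table["sp1"]["RLK"] == 1
        assert table["sp1"]["RLP"] == 1
        assert table["sp1"]["gene_content"] == 3
        assert table["sp2"]["LYSM_RLK"] == 1

    def test_zero_rga_species(self):
        table = compare_family_sizes({"sp": {"g1": "NON_RGA"}})
        assert table["sp"]["RLK"] == 0 and table["sp"]["RLP"] == 0

    def test_requires_at_least_one_species(self):
        with pytest.raises(ValueError):
            compare_family_sizes({})

    def test_paper_fixture_species_totals(self, paper_bundle):
        table = compare_family_sizes(
            {s: r.classification for s, r in paper_bundle.species.items()}
        )
        assert table["tetraploid"]["RLK"] == 493
        assert table["tetraploid"]["gene_content"] == 80_430
        assert table["progenitor_A"]["RLK"] == 300
        assert table["progenitor_A"]["gene_content"] == 46_098
        assert table["progenitor_B"]["RLP"] == 176
        assert table["progenitor_B"]["gene_content"] == 49_826
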