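"""Seven-gene sliding-window PUL prediction."""

import numpy as np
import pytest

from _oracles import as_tuples, brute_force_pul_calls, make_random_contig
from conftest import contig_from_spec
from pulloop.errors import ParameterError
from pulloop.pul_caller import call_puls, find_suscd_pairs


def _genes(ann):
    return ann.contigs["c1"]


class TestSusCDPairs:
    def test_adjacent_same_strand_pair(self):
        ann = contig_from_spec([{}, {}, {}, {"role": "susC"}, {"role": "susD"}])
        assert find_suscd_pairs(_genes(ann)) == [("T_0003", "T_0004")]

    def test_strand_mismatch_blocks_pair(self):
        ann = contig_from_spec(
            [{}, {}, {}, {"role": "susC"}, {"role": "susD", "strand": "-"}]
        )
        assert find_suscd_pairs(_genes(ann)) == []

    def test_gap_beyond_pair_gap_blocks_pair(self):
        ann = contig_from_spec(
            [{}, {}, {}, {"role": "susC"}, {}, {}, {"role": "susD"}]
        )
        assert find_suscd_pairs(_genes(ann)) == []

    def test_wider_pair_gap_allows_one_intervening_gene(self):
        ann = contig_from_spec([{"role": "susC"}, {}, {"role": "susD"}])
        assert find_suscd_pairs(_genes(ann), pair_gap=2) == [("T_0000", "T_0002")]

    def test_each_gene_joins_at_most_one_pair(self):
        ann = contig_from_spec(
            [{"role": "susC"}, {"role": "susD"}, {"role": "susD"}]
        )
        assert find_suscd_pairs(_genes(ann)) == [("T_0000", "T_0001")]

    def test_susd_first_order_also_pairs(self):
        ann = contig_from_spec([{"role": "susD"}, {"role": "susC"}])
        assert find_suscd_pairs(_genes(ann)) == [("T_0001", "T_0000")]


class TestCallPuls:
    def test_canonical_locus_members_and_inventory(self):
        ann = contig_from_spec(
            [{}, {"role": "susC"}, {"role": "susD"}, {"fam": "GH13"}, {},
             {"fam": "GH65"}]
        )
        (pul,) = call_puls(ann)
        assert pul.first_gene_index == 1
        assert pul.last_gene_index == 5
        assert pul.member_locus_tags == [f"T_{i:04d}" for i in range(1, 6)]
        assert pul.cazyme_inventory == ("GH13", "GH65")
        assert pul.suscd_pairs == [("T_0001", "T_0002")]
        assert pul.substrate == "other" and pul.susd_type == "not_typed"

    def test_cazyme_beyond_window_leaves_component_unemitted(self):
        specs = [{} for _ in range(20)]
        specs[10] = {"role": "susC"}
        specs[11] = {"role": "susD"}
        specs[19] = {"fam": "GH13"}
        assert call_puls(contig_from_spec(specs)) == []

    def test_wider_window_joins_distant_cazyme(self):
        specs = [{} for _ in range(20)]
        specs[10] = {"role": "susC"}
        specs[11] = {"role": "susD"}
        specs[19] = {"fam": "GH13"}
        (pul,) = call_puls(contig_from_spec(specs), window=8)
        assert (pul.first_gene_index, pul.last_gene_index) == (10, 19)

    def test_cazymes_without_pair_never_emit(self):
        ann = contig_from_spec([{"fam": "GH13"}, {}, {"fam": "GH13"}])
        assert call_puls(ann) == []

    def test_pair_with_only_binding_modules_never_emits(self):
        # CBM/GT tokens are anchors but do not satisfy the enzyme requirement
        ann = contig_from_spec(
            [{"role": "susC"}, {"role": "susD"}, {"fam": "CBM48"}, {"fam": "GT2"}]
        )
        assert call_puls(ann) == []

    def test_bad_window_rejected(self):
        ann = contig_from_spec([{}])
        with pytest.raises(ParameterError):
            call_puls(ann, window=0)

    def test_bp_span_covers_member_genes(self):
        ann = contig_from_spec(
            [{"role": "susC", "start": 101, "end": 500},
             {"role": "susD", "start": 601, "end": 1200},
             {"fam": "GH13", "start": 1301, "end": 2000}]
        )
        (pul,) = call_puls(ann)
        assert (pul.start, pul.end) == (101, 2000)


def test_matches_bruteforce_on_random_contigs(rng):
    for _ in range(200):
        ann = make_random_contig(rng, int(rng.integers(1, 31)))
        got = as_tuples(call_puls(ann))
        expected = sorted(brute_force_pul_calls(ann.contigs["c1"]))
        assert [g[:3] for g in got] == [e[:3] for e in expected]
        assert [sorted(g[3]) for g in got] == [sorted(e[3]) for e in expected]


def test_window_monotonicity_on_random_contigs(rng):
    """Anchor genes covered by emitted PULs are nested non-decreasing in w."""
    for _ in range(50):
        ann = make_random_contig(rng, int(rng.integers(5, 31)))
        covered_prev: set[int] = set()
        for w in range(1, 11):
            covered = {
                i
                for p in call_puls(ann, window=w)
                for i in range(p.first_gene_index, p.last_gene_index + 1)
            }
            assert covered_prev <= covered
            covered_prev = covered


def _mirror(ann):
    genes = ann.contigs["c1"]
    total = max(g.end for g in genes) + 1
    flipped = []
    for j, g in enumerate(reversed(genes)):
        flipped.append(
            type(g)(
                genome_id=g.genome_id,
                contig_id=g.contig_id,
                gene_index=j,
                start=total - g.end,
                end=total - g.start,
                strand="-" if g.strand == "+" else "+",
                locus_tag=g.locus_tag,
                cazy_families=g.cazy_families,
                k_numbers=g.k_numbers,
                sus_role=g.sus_role,
            )
        )
    return type(ann)(genome_id=ann.genome_id, contigs={"c1": flipped})


def test_mirror_symmetry(rng):
    """Reversing gene order and flipping strands maps PULs one-to-one."""
    for _ in range(100):
        ann = make_random_contig(rng, int(rng.integers(2, 31)))
        fwd = call_puls(ann)
        rev = call_puls(_mirror(ann))
        fwd_members = sorted(frozenset(p.member_locus_tags) for p in fwd)
        rev_members = sorted(frozenset(p.member_locus_tags) for p in rev)
        assert fwd_members == rev_members


def test_planted_recovery_on_small_cohort(small_cohort):
    _, annotations, truth = small_cohort
    called = {
        (p.genome_id, p.contig_id, p.first_gene_index, p.last_gene_index)
        for ann in annotations.values()
        for p in call_puls(ann)
    }
    planted = {
        (p.genome_id, p.contig_id, p.first_gene_index, p.last_gene_index)
        for p in truth.puls
    }
    assert called == planted
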