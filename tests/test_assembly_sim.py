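"""SapI digestion geometry, Golden Gate enumeration and Gibson checks.

The digestion oracle is the enzyme definition applied by hand: GCTCTTC
with (1/4) geometry — top-strand cut after 1 spacer nt, bottom after 4 —
leaving 3-nt 5' overhangs.  Toy molecules are built with sites at known
positions so every cut coordinate is computed on paper in the test.
"""

import numpy as np
import pytest

from promoswap import (
    AssemblyError,
    ElementLayout,
    Plasmid,
    build_element,
    extract_arms,
    gibson_check,
    golden_gate,
    make_part,
    reconstruct_edited_locus,
    revcomp,
    sapi_digest,
)
from promoswap.assembly_sim import ligate_circular, part_insert
from promoswap.construct_design import count_sapi_sites
from promoswap.fixtures import make_basic_plasmid, make_promoter_parts, make_vector

from test_construct_design import clean_locus, make_guide


def rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestSapiDigest:
    def test_no_sites_circular_returned_unchanged(self):
        p = Plasmid("p", "ACGTAC" * 30, circular=True)
        frags = sapi_digest(p)
        assert len(frags) == 1 and frags[0].sequence == p.sequence
        assert frags[0].circular

    def test_forward_site_linear_cut_coordinates(self):
        """Site GCTCTTC at 0-based 10: top cut after index 17 (1 spacer nt),
        bottom after index 20, so the right fragment starts at 18 with 5'
        overhang seq[18:21]."""
        rng = np.random.default_rng(3)
        seq = rand_dna(rng, 10) + "GCTCTTC" + rand_dna(rng, 40)
        assert count_sapi_sites(seq) == 1
        left, right = sapi_digest(Plasmid("p", seq, circular=False))
        assert left.sequence == seq[:18]
        assert right.sequence == seq[18:]
        assert left.right_overhang == right.left_overhang == seq[18:21]
        assert left.left_overhang == "" and right.right_overhang == ""

    def test_reverse_site_linear_cut_coordinates(self):
        """GAAGAGC at 0-based 20 cuts leftward: top cut before index 16,
        bottom before index 19; junction 3-mer is seq[16:19]."""
        rng = np.random.default_rng(4)
        seq = rand_dna(rng, 20) + "GAAGAGC" + rand_dna(rng, 30)
        left, right = sapi_digest(Plasmid("p", seq, circular=False))
        assert left.sequence == seq[:16]
        assert right.sequence == seq[16:]
        assert left.right_overhang == right.left_overhang == seq[16:19]

    def test_element_cassette_plasmid_two_fragments(self, toy_designs, toy_vector):
        d = next(iter(toy_designs.values()))
        plasmid = make_basic_plasmid(d.element, d.arms, toy_vector)
        frags = sapi_digest(plasmid)
        assert len(frags) == 2
        by_ov = {(f.left_overhang, f.right_overhang) for f in frags}
        assert by_ov == {("ATG", "AAT"), ("AAT", "ATG")}
        backbone = next(f for f in frags if f.left_overhang == "ATG")
        assert backbone.sequence.endswith(d.arms.up_arm.seq)
        assert backbone.sequence.startswith("ATG")

    def test_flanked_part_three_fragments(self):
        part = make_part("P", "ACGTTGCA" * 10, o_up="AAT")
        frags = sapi_digest(Plasmid("P", part.flanked_seq, circular=False))
        assert len(frags) == 3
        mid = frags[1]
        assert (mid.left_overhang, mid.right_overhang) == ("AAT", "ATG")
        assert mid.sequence == "AAT" + part.core_seq

    def test_overlapping_recognition_sites_rejected(self):
        # GAAGAGCTCTTC carries a reverse site at offset 0 and a forward
        # site at offset 5: the recognition footprints overlap
        seq = "A" * 20 + "GAAGAGCTCTTC" + "A" * 20
        assert count_sapi_sites(seq) == 2
        with pytest.raises(AssemblyError, match="overlap"):
            sapi_digest(Plasmid("p", seq, circular=False))

    def test_rotation_invariance_on_circular(self, toy_designs, toy_vector):
        d = next(iter(toy_designs.values()))
        plasmid = make_basic_plasmid(d.element, d.arms, toy_vector)
        seq = plasmid.sequence
        for shift in (1, 97, len(seq) // 2):
            rotated = seq[shift:] + seq[:shift]
            frags = sapi_digest(Plasmid("r", rotated, circular=True))
            assert len(frags) == 2
            assert {(f.left_overhang, f.right_overhang) for f in frags} == \
                {("ATG", "AAT"), ("AAT", "ATG")}

    def test_digest_ligate_round_trip(self, toy_designs, toy_vector):
        """Re-ligating backbone and stuffer regenerates the plasmid exactly
        (up to rotation of the circular sequence)."""
        d = next(iter(toy_designs.values()))
        plasmid = make_basic_plasmid(d.element, d.arms, toy_vector)
        a, b = sapi_digest(plasmid)
        regenerated = ligate_circular(a, b)
        doubled = plasmid.sequence * 2
        assert len(regenerated) == len(plasmid.sequence)
        assert regenerated in doubled


class TestMakePart:
    def test_digest_yields_expected_insert_span(self):
        core = "ACGTTGCA" * 15  # 120 nt
        part = make_part("P", core, "AAT")
        ins = part_insert(part)
        # top strand = o_up + core; the physical fragment spans 120+3+3 bases
        assert len(ins.sequence) == 123
        assert len(ins.sequence) + len(ins.right_overhang) == 126

    def test_core_with_reverse_site_rejected(self):
        with pytest.raises(AssemblyError, match="SapI"):
            make_part("P", "ACGT" + "GAAGAGC" + "ACGT")

    def test_empty_core_is_deletion_part(self):
        part = make_part("DELETION", "", "AAT")
        ins = part_insert(part)
        assert ins.sequence == "AAT"
        assert (ins.left_overhang, ins.right_overhang) == ("AAT", "ATG")

    def test_atg_scar_rejected(self):
        with pytest.raises(AssemblyError, match="ATG"):
            make_part("P", "ACGTACGT", o_up="ATG")


class TestGoldenGate:
    def test_diversity_counts(self, toy_pool):
        """8 targets x (6 promoters + deletion) = 56 distinct products."""
        assert toy_pool.diversity == 56
        assert len(toy_pool.products) == 56
        assert not toy_pool.failures

    def test_single_backbone_single_part_no_deletion(self, toy_designs, toy_vector, toy_parts):
        d = next(iter(toy_designs.values()))
        basic = make_basic_plasmid(d.element, d.arms, toy_vector)
        pool = golden_gate([basic], toy_parts[:1], include_deletion=False)
        assert pool.diversity == 1
        pr = pool.products[0]
        assert pr.promoter_id == toy_parts[0].id

    def test_mismatched_overhang_part_excluded(self, toy_designs, toy_vector, toy_parts):
        d = next(iter(toy_designs.values()))
        basic = make_basic_plasmid(d.element, d.arms, toy_vector)
        odd = make_part("ODD", "ACGTTGCA" * 8, o_up="GGG")
        with pytest.warns(UserWarning, match="incompatible"):
            pool = golden_gate([basic], list(toy_parts) + [odd], include_deletion=False)
        assert pool.diversity == len(toy_parts)
        assert "ODD" not in {p.promoter_id for p in pool.products}

    def test_products_are_sapi_free_and_redigest_unchanged(self, toy_pool):
        for pr in toy_pool.products[:8]:
            assert count_sapi_sites(pr.sequence, circular=True) == 0
            frags = sapi_digest(Plasmid(pr.id, pr.sequence, circular=True))
            assert len(frags) == 1 and frags[0].sequence == pr.sequence

    def test_junction_layout(self, toy_designs, toy_pool):
        """Every product reads up_arm . scar . core . ATG . down_arm[3:]."""
        for pr in toy_pool.products:
            d = toy_designs[pr.target_id]
            junction = (d.arms.up_arm.seq + "AAT" + (pr.meta or {})["core"]
                        + d.arms.down_arm.seq)
            assert junction in pr.sequence * 2


class TestGibsonCheck:
    def test_matching_backbone_passes_20_20(self, toy_designs, toy_vector):
        d = next(iter(toy_designs.values()))
        rep = gibson_check(d.element, toy_vector, toy_vector)
        assert rep.passed and (rep.left_overlap, rep.right_overlap) == (20, 20)

    def test_one_terminal_mismatch_gives_19(self, toy_designs, toy_vector):
        d = next(iter(toy_designs.values()))
        el = d.element
        mutated = type(el)(el.target_id,
                           ("T" if el.sequence[0] != "T" else "A") + el.sequence[1:],
                           el.features)
        rep = gibson_check(mutated, toy_vector, toy_vector)
        assert not rep.passed and rep.left_overlap == 19

    def test_too_short_element_fails(self, toy_vector):
        from promoswap import SyntheticElement
        short = SyntheticElement("s", "ACGT" * 5, [])
        rep = gibson_check(short, toy_vector, toy_vector)
        assert not rep.passed and "too short" in rep.reason


class TestReconstructEditedLocus:
    def test_cds_starts_at_original_atg(self, toy_designs, toy_pool):
        for pr in toy_pool.products[:10]:
            d = toy_designs[pr.target_id]
            edited = reconstruct_edited_locus(pr, d.locus)
            idx = d.arms.up_arm.start + d.locus.u
            cds_at = idx + len(d.arms.up_arm.seq) + 3 + len((pr.meta or {})["core"])
            assert edited[cds_at:cds_at + 3] == "ATG"
            # downstream of the ATG the CDS is untouched
            assert edited[cds_at:] == d.locus.window_seq[d.locus.u:]

    def test_deletion_reconstruction_is_concatenation(self, toy_designs, toy_pool):
        pr = next(p for p in toy_pool.products if p.promoter_id == "DELETION")
        d = toy_designs[pr.target_id]
        edited = reconstruct_edited_locus(pr, d.locus)
        expected = d.arms.up_arm.seq + "AAT" + d.locus.window_seq[d.locus.u:]
        assert edited == expected  # up arm starts at the window edge (-500)

    def test_length_bookkeeping_across_promoters(self, toy_designs, toy_pool):
        """Swapping in cores of different length shifts the edited locus
        length by exactly the core-length difference."""
        target = next(iter(toy_designs))
        d = toy_designs[target]
        prods = [p for p in toy_pool.products if p.target_id == target]
        lengths = {p.promoter_id: len(reconstruct_edited_locus(p, d.locus))
                   for p in prods}
        cores = {p.promoter_id: len((p.meta or {})["core"]) for p in prods}
        base = lengths["DELETION"] - cores["DELETION"]
        for pid in lengths:
            assert lengths[pid] == base + cores[pid]
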