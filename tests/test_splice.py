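"""The splicing state machine: precursors, cis/back-splicing, intron circles,
junction enumeration, nucleotide conservation."""

import numpy as np
import pytest

from mitosplice import (
    ChemistryError,
    CircularGenome,
    InputError,
    IntronModel,
    JunctionCategory,
    SpeciesClass,
    back_splice,
    build_conventional_precursor,
    build_permuted_precursor,
    circularize_intron,
    cis_splice,
    enumerate_junctions,
    revcomp,
    validate_intron,
)
from tests.conftest import make_toy


class TestValidateIntron:
    def test_omega_g_all_pass(self, rng):
        genome, intron = make_toy(rng)
        seq = genome.sequence[:-1] + "G"  # omega position is L-1 (three_ss=0)
        genome = CircularGenome("toy", seq)
        checks = validate_intron(genome, intron)
        assert all(c.status == "pass" for c in checks)

    def test_omega_a_warns_not_fails(self, rng):
        genome, intron = make_toy(rng)
        genome = CircularGenome("toy", genome.sequence[:-1] + "A")
        checks = validate_intron(genome, intron)
        by_name = {c.name: c for c in checks}
        assert by_name["omega-chemistry"].status == "warn"
        assert "A" in by_name["omega-chemistry"].message
        assert not any(c.status == "fail" for c in checks)

    def test_zero_length_intron_fails(self, rng):
        genome, _ = make_toy(rng)
        intron = IntronModel(id="z", five_ss=15, three_ss=15, exon1_start=10, exon2_end=20)
        checks = validate_intron(genome, intron)
        assert any(c.status == "fail" and "zero-length" in c.message for c in checks)


class TestConventional:
    def test_toy_lengths(self, toy):
        genome, intron = toy  # exon1 [10,15): 5 nt; intron [15,0): 25 nt
        prec = build_conventional_precursor(genome, intron, pad=5)
        assert len(prec) == 5 + 25 + 5
        assert prec.species_class == SpeciesClass.PRECURSOR_CONVENTIONAL

    def test_pad_zero_rejected(self, toy):
        genome, intron = toy
        with pytest.raises(InputError):
            build_conventional_precursor(genome, intron, pad=0)

    def test_pad_exceeding_exon_rejected(self, toy):
        genome, intron = toy
        with pytest.raises(InputError):
            build_conventional_precursor(genome, intron, pad=7)  # exon2 only 6 nt

    def test_cis_splice_products(self):
        # exon1 AAAAA, 25-nt intron ending G, exon2 CCCCCC
        seq = "CCCCCC" + "GTAT" + "AAAAA" + "T" * 24 + "G"
        genome = CircularGenome("t", seq)
        intron = IntronModel(id="i", five_ss=15, three_ss=0, exon1_start=10, exon2_end=6)
        prec = build_conventional_precursor(genome, intron, pad=5)
        mrna, intron_product = cis_splice(prec, intron, genome)
        assert mrna.sequence == "AAAAACCCCC"
        assert intron_product.sequence.startswith("G")  # the exo-G
        assert len(intron_product) == 26
        assert len(prec) == len(mrna) + (len(intron_product) - 1)
        assert mrna.junctions[0].category == JunctionCategory.E1E2_LIGATION

    def test_cis_requires_conventional_precursor(self, toy):
        genome, intron = toy
        perm = build_permuted_precursor(genome, intron, tx_start=35, tx_end=20)
        with pytest.raises(InputError):
            cis_splice(perm, intron, genome)


class TestPermuted:
    def test_toy_walk_length(self, toy):
        genome, intron = toy
        prec = build_permuted_precursor(genome, intron, tx_start=35, tx_end=20)
        assert len(prec) == 25  # 5 + 6 + 4 + 5 + 5
        assert prec.transcript.segments == (
            (35, 0), (0, 6), (6, 10), (10, 15), (15, 20))

    def test_tx_start_inside_exon2_rejected(self, toy):
        genome, intron = toy
        with pytest.raises(InputError):
            build_permuted_precursor(genome, intron, tx_start=3, tx_end=20)

    def test_tx_ordering_violation_rejected(self, toy):
        genome, intron = toy
        with pytest.raises(InputError):
            build_permuted_precursor(genome, intron, tx_start=20, tx_end=35)

    def test_back_splice_bookkeeping(self, toy):
        genome, intron = toy
        prec = build_permuted_precursor(genome, intron, tx_start=35, tx_end=20)
        circ, seg3, seg5 = back_splice(prec, intron, genome)
        assert (len(circ), len(seg3), len(seg5)) == (15, 5, 6)
        assert len(prec) == len(circ) + len(seg3) + (len(seg5) - 1)
        assert circ.transcript.topology == "circular"
        assert seg5.sequence.startswith("G")
        assert seg5.extra_5p == "G" and seg3.extra_5p == ""

    def test_back_splice_requires_permuted(self, toy):
        genome, intron = toy
        conv = build_conventional_precursor(genome, intron, pad=4)
        with pytest.raises(InputError):
            back_splice(conv, intron, genome)

    def test_circ_closure_is_the_ligation_junction(self, toy_big):
        genome, intron = toy_big
        prec = build_permuted_precursor(genome, intron, tx_start=50, tx_end=40)
        circ, _, _ = back_splice(prec, intron, genome)
        k = 6
        juncs = enumerate_junctions(genome, intron, k=k)
        e1e2 = next(j for j in juncs if j.category == JunctionCategory.E1E2_LIGATION)
        # closure of the circle: last k nt + first k nt
        s = circ.sequence
        assert s[-k:] == e1e2.left_flank and s[:k] == e1e2.right_flank


class TestCircularization:
    def _intron_product(self, rng, omega):
        genome, intron = make_toy(rng, L=60, e2_end=10, linker_end=16,
                                  e1_start=16, five_ss=28)
        genome = CircularGenome("t", genome.sequence[:-1] + omega)
        prec = build_conventional_precursor(genome, intron, pad=6)
        _, product = cis_splice(prec, intron, genome)
        return genome, intron, product

    def test_full_circle_length(self, rng):
        genome, intron, product = self._intron_product(rng, "G")
        circle = circularize_intron(product, intron, genome, donor_offset=0)
        assert len(circle) == intron.length(genome)
        assert circle.species_class == SpeciesClass.INTRON_CIRCLE_FULL

    def test_truncated_circle_lengths_decrease(self, rng):
        genome, intron, product = self._intron_product(rng, "G")
        sizes = [len(circularize_intron(product, intron, genome, donor_offset=d))
                 for d in (0, 5, 10, 15)]
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[0] - sizes[1] == 5

    def test_omega_a_chemistry_error(self, rng):
        genome, intron, product = self._intron_product(rng, "A")
        with pytest.raises(ChemistryError, match="omega-G"):
            circularize_intron(product, intron, genome)
        forced = circularize_intron(product, intron, genome, force=True)
        assert forced.species_class == SpeciesClass.INTRON_CIRCLE_FULL

    def test_offset_out_of_range(self, rng):
        genome, intron, product = self._intron_product(rng, "G")
        with pytest.raises(InputError):
            circularize_intron(product, intron, genome, donor_offset=1000)


class TestEnumerateJunctions:
    def test_contexts_match_string_slicing(self, toy_big):
        genome, intron = toy_big  # exon2 [0,10), exon1 [16,28), intron [28,0)
        k = 6
        s = genome.sequence
        juncs = {j.category: j for j in enumerate_junctions(genome, intron, k=k)}
        assert juncs[JunctionCategory.E1E2_LIGATION].context == s[22:28] + s[0:6]
        assert juncs[JunctionCategory.UNSPLICED_5SS].context == s[22:28] + s[28:34]
        assert juncs[JunctionCategory.UNSPLICED_3SS].context == s[-6:] + s[0:6]
        assert juncs[JunctionCategory.PERMUTED_GENOMIC].context == s[4:10] + s[10:16]

    def test_circle_offsets(self, toy_big):
        genome, intron = toy_big
        juncs = enumerate_junctions(genome, intron, k=6, circle_offsets=(0, 7))
        circles = [j for j in juncs if j.category == JunctionCategory.INTRON_CIRCLE]
        s = genome.sequence
        assert [j.donor_offset for j in circles] == [0, 7]
        assert circles[0].right_flank == s[28:34]
        assert circles[1].right_flank == s[35:41]

    def test_k_larger_than_exon_rejected(self, toy_big):
        genome, intron = toy_big
        with pytest.raises(InputError):
            enumerate_junctions(genome, intron, k=11)  # exon2 is 10 nt

    def test_pathways_share_the_ligation_junction(self, toy_big):
        """cis-splicing of the conventional precursor and back-splicing of the
        permuted one create the identical exon-ligation context — the reason
        junction reads alone cannot distinguish the pathways."""
        genome, intron = toy_big
        k = 6
        conv = build_conventional_precursor(genome, intron, pad=8)
        mrna, _ = cis_splice(conv, intron, genome)
        perm = build_permuted_precursor(genome, intron, tx_start=55, tx_end=35)
        circ, _, _ = back_splice(perm, intron, genome)
        i = mrna.junctions[0].offset
        mrna_ctx = mrna.sequence[i - k : i + k]
        circ_ctx = circ.sequence[-k:] + circ.sequence[:k]
        assert mrna_ctx == circ_ctx


def random_layout(rng):
    """Random toy layout on a random circle; returns (genome, intron, pads)."""
    e2 = int(rng.integers(6, 15))
    linker = int(rng.integers(0, 8))
    e1 = int(rng.integers(6, 15))
    intron_len = int(rng.integers(12, 60))
    L = e2 + linker + e1 + intron_len
    genome, _ = make_toy(rng, L=L)
    intron = IntronModel(id="r", five_ss=e2 + linker + e1, three_ss=0,
                         exon1_start=e2 + linker, exon2_end=e2)
    return genome, intron, e2, linker, e1, intron_len


def test_conservation_on_random_layouts(rng):
    """Nucleotide bookkeeping of both pathways on 200 random toy genomes
    (the full 1000-genome sweep runs in the acceptance suite)."""
    for _ in range(200):
        genome, intron, e2, linker, e1, ilen = random_layout(rng)
        pad = int(rng.integers(1, min(e1, e2) + 1))
        conv = build_conventional_precursor(genome, intron, pad)
        mrna, product = cis_splice(conv, intron, genome)
        assert len(conv) == len(mrna) + (len(product) - 1)
        assert mrna.sequence == conv.sequence[:pad] + conv.sequence[-pad:]
        assert product.sequence == "G" + conv.sequence[pad:-pad]

        margin = int(rng.integers(1, ilen // 2))
        L = genome.length
        tx_start = (intron.three_ss - margin) % L
        tx_end = (intron.five_ss + margin) % L
        perm = build_permuted_precursor(genome, intron, tx_start, tx_end)
        circ, seg3, seg5 = back_splice(perm, intron, genome)
        assert len(perm) == len(circ) + len(seg3) + (len(seg5) - 1)
        assert seg3.sequence == perm.sequence[:margin]
        assert seg5.sequence == "G" + perm.sequence[-margin:]
        assert circ.sequence == perm.sequence[margin:-margin]


def test_species_sequence_reproducible_from_segments(toy):
    genome, intron = toy
    perm = build_permuted_precursor(genome, intron, tx_start=35, tx_end=20)
    for sp in (perm, *back_splice(perm, intron, genome)):
        rebuilt = sp.extra_5p + "".join(
            genome.subsequence(s, e) for s, e in sp.transcript.segments
        )
        assert rebuilt == sp.sequence
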