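"""Junction library, read classification, feature assignment, co-occurrence
evidence for back-splicing."""

import numpy as np
import pytest

from mitosplice import (
    CircularGenome,
    Feature,
    FeatureAssigner,
    InputError,
    Junction,
    JunctionCategory,
    SpeciesClass,
    build_junction_library,
    classify_read,
    classify_reads,
    count_by_category,
    detect_backsplice_support,
    enumerate_junctions,
    revcomp,
    simulate_reads,
)
from mitosplice.classify import AMBIGUOUS, ASSIGNED, UNASSIGNED


def _mk_junction(rng, category="E1E2_LIGATION", intron="i1", k=10):
    flanks = "".join(rng.choice(list("ACGT"), size=2 * k))
    return Junction(category, flanks[:k], flanks[k:], intron)


class TestLibrary:
    def test_entries_have_2k_contexts(self, rng):
        juncs = [_mk_junction(rng, c, "i1") for c in
                 ("E1E2_LIGATION", "UNSPLICED_5SS", "UNSPLICED_3SS", "PERMUTED_GENOMIC")]
        lib = build_junction_library(juncs, k=10)
        assert len(lib) == 4
        assert all(len(e.context) == 20 for e in lib.entries)

    def test_duplicate_contexts_collapse(self, rng):
        j1 = _mk_junction(rng, "E1E2_LIGATION", "i1")
        j2 = Junction("UNSPLICED_5SS", j1.left_flank, j1.right_flank, "i2")
        lib = build_junction_library([j1, j2], k=10)
        assert len(lib) == 1
        assert len(lib.entries[0].categories) == 2

    def test_empty_library(self):
        assert len(build_junction_library([], k=10)) == 0

    def test_inconsistent_k_rejected(self, rng):
        with pytest.raises(InputError):
            build_junction_library([_mk_junction(rng, k=8)], k=10)


class TestClassifyRead:
    def test_central_window_exact_match(self, rng):
        lib = build_junction_library([_mk_junction(rng)], k=10)
        ctx = lib.entries[0].context
        a = classify_read(ctx[10 - 10 : 10 + 10], lib, min_overlap=10)
        assert a.outcome == ASSIGNED and a.mismatches == 0
        assert a.left_overlap >= 10 and a.right_overlap >= 10

    def test_left_flank_only_unassigned(self, rng):
        lib = build_junction_library([_mk_junction(rng)], k=10)
        ctx = lib.entries[0].context
        read = ctx[:10] + "".join(rng.choice(list("ACGT"), size=30))
        # matching stops at the midpoint: no right-side overlap
        a = classify_read(read, lib, min_overlap=10, max_mismatch_rate=0.04)
        assert a.outcome in (UNASSIGNED,)

    def test_equal_match_to_two_junctions_is_ambiguous(self, rng):
        # both contexts share the central 16 nt but differ outside it
        shared = "".join(rng.choice(list("ACGT"), size=16))
        j1 = Junction("E1E2_LIGATION", "AA" + shared[:8], shared[8:] + "AA", "i1")
        j2 = Junction("UNSPLICED_5SS", "CC" + shared[:8], shared[8:] + "CC", "i2")
        lib = build_junction_library([j1, j2], k=10)
        a = classify_read(shared, lib, min_overlap=6)
        assert a.outcome == AMBIGUOUS

    def test_short_read_unassigned(self, rng):
        lib = build_junction_library([_mk_junction(rng)], k=10)
        assert classify_read("ACGTACGT", lib, min_overlap=10).outcome == UNASSIGNED

    def test_revcomp_invariance(self, study):
        lib = study["lib"]
        genome, introns = study["genome"], study["introns"]
        juncs = study["junctions"]
        rng = np.random.default_rng(3)
        for j in juncs:
            read = j.context
            a_fwd = classify_read(read, lib)
            a_rev = classify_read(revcomp(read), lib)
            assert a_fwd.outcome == a_rev.outcome
            assert a_fwd.junction_id == a_rev.junction_id

    def test_simulated_junction_reads_assigned(self, study):
        """200-nt reads over the ligation junction with 1% substitutions are
        recovered in the overwhelming majority of 1000 seeded trials.

        The attainable rate is bounded by the alignment acceptance rule
        itself: the aligned span is the 50-nt context window, and a read is
        rejected when 3+ of its errors land there, which at a 1% per-base
        rate happens with probability ~1.4% (Binomial(50, 0.01)).  The bound
        below allows that rejection rate plus Monte-Carlo noise."""
        genome, introns = study["genome"], study["introns"]
        giant = introns[0]
        lib = study["lib"]
        e1e2 = next(j for j in study["junctions"]
                    if j.category == JunctionCategory.E1E2_LIGATION
                    and j.intron_id == giant.id)
        L = genome.length
        # the ligated neighbourhood: 200 nt of exon1 tail + exon2 head
        region = (genome.subsequence((giant.five_ss - 120) % L, giant.five_ss)
                  + genome.subsequence(giant.three_ss, (giant.three_ss + 120) % L))
        rng = np.random.default_rng(42)
        ok = 0
        n_trials = 1000
        for _ in range(n_trials):
            start = int(rng.integers(0, 40))  # junction stays >=10 nt inside
            read = list(region[start : start + 200])
            errs = rng.random(200) < 0.01
            for i in np.nonzero(errs)[0]:
                read[i] = "ACGT"[(("ACGT".index(read[i])) + int(rng.integers(1, 4))) % 4]
            a = classify_read("".join(read), lib, min_overlap=10, max_mismatch_rate=0.04)
            ok += (a.outcome == ASSIGNED
                   and a.categories[0][0] == JunctionCategory.E1E2_LIGATION)
        assert ok / n_trials >= 0.97

    def test_batch_equals_per_read(self, study):
        reads, _ = simulate_reads(study["pool"], study["cfg"], seed=77)
        subset = [(r[0], r[1]) for r in reads[:400]]
        batch = classify_reads(subset, study["lib"])
        for (rid, seq), a in zip(subset, batch):
            b = classify_read(seq, study["lib"], read_id=rid)
            assert (a.outcome, a.junction_id) == (b.outcome, b.junction_id)


def test_error_free_reads_recover_truth(study):
    """Every error-free read spanning a junction midpoint with >= m nt both
    sides is assigned to exactly its true category (simulator truth as oracle)."""
    from mitosplice import SimConfig

    cfg = SimConfig(seed=5, n_reads=4000, substitution_rate=0.0)
    reads, truths = simulate_reads(study["pool"], cfg, seed=5)
    assignments = classify_reads([(r[0], r[1]) for r in reads], study["lib"])
    by_id = {t.read_id: t for t in truths}
    n_junctional = 0
    for a in assignments:
        t = by_id[a.read_id]
        if t.junction_category is not None:
            n_junctional += 1
            assert a.outcome == ASSIGNED, (t, a)
            assert a.categories[0][0] == t.junction_category
            assert a.categories[0][1] == t.junction_intron
        else:
            assert not (a.outcome == ASSIGNED and a.mismatches == 0
                        and a.categories and a.categories[0][0] != "PERMUTED_GENOMIC"
                        and t.species_class == SpeciesClass.GENIC_OTHER)
    assert n_junctional > 20  # the oracle actually exercised junction reads


def test_counts_conservation(study):
    reads, _ = simulate_reads(study["pool"], study["cfg"], seed=13)
    assignments = classify_reads([(r[0], r[1]) for r in reads], study["lib"])
    counts = count_by_category(assignments)
    assert counts.total == len(reads)
    assert counts.conserved()


class TestFeatureAssigner:
    def test_verbatim_read_hits_its_feature(self, study):
        genome = study["genome"]
        feats = [f for f in study["features"] if f.id in {"SSU", "LSU", "ND1"}]
        assigner = FeatureAssigner(genome, feats)
        read = genome.subsequence(2100, 2300)  # inside SSU [2000, 3500)
        a = assigner.assign(read)
        assert a.outcome == ASSIGNED and a.feature_id == "SSU" and a.strand == "+"

    def test_majority_feature_wins(self, study):
        genome = study["genome"]
        feats = [Feature("left", "CDS", 6200, 7150), Feature("right", "CDS", 7150, 8000)]
        assigner = FeatureAssigner(genome, feats)
        read = genome.subsequence(7030, 7230)  # 120 nt left / 80 nt right
        a = assigner.assign(read)
        assert a.outcome == ASSIGNED and a.feature_id == "left"

    def test_aorf_strand_read(self, study):
        genome = study["genome"]
        aorf = next(f for f in study["features"] if f.ftype == "aORF")
        assigner = FeatureAssigner(genome, [aorf])
        rna = revcomp(genome.subsequence(aorf.start, aorf.end))  # the aORF transcript
        a = assigner.assign(rna[:200])
        assert a.outcome == ASSIGNED and a.feature_id == aorf.id and a.strand == "-"

    def test_wrapping_read_places(self, study):
        genome = study["genome"]
        L = genome.length
        feats = [Feature("tail", "CDS", L - 300, 100)]
        assigner = FeatureAssigner(genome, feats)
        read = genome.subsequence(L - 150, 50)
        a = assigner.assign(read)
        assert a.outcome == ASSIGNED and a.feature_id == "tail"

    def test_foreign_read_unassigned(self, study, rng):
        genome = study["genome"]
        assigner = FeatureAssigner(genome, study["features"][:3])
        read = "".join(rng.choice(list("ACGT"), size=200))
        assert assigner.assign(read).outcome == UNASSIGNED


class TestBacksplicSupport:
    def test_circular_intermediate_supports_at_any_rotation(self, study, rng):
        genome, introns, pool = study["genome"], study["introns"], study["pool"]
        giant = introns[0]
        circ = next(e.species for e in pool
                    if e.species.species_class == SpeciesClass.CIRC_INTERMEDIATE)
        s = circ.sequence
        for _ in range(10):
            rot = int(rng.integers(0, len(s)))
            doubled = (s[rot:] + s[:rot]) * 2
            n, ev = detect_backsplice_support([("r", doubled)], giant, genome)
            assert n == 1 and ev[0].supports

    def test_ligated_exons_alone_insufficient(self, study):
        genome, introns = study["genome"], study["introns"]
        giant = introns[0]
        L = genome.length
        mrna_like = (genome.subsequence((giant.five_ss - 200) % L, giant.five_ss)
                     + genome.subsequence(giant.three_ss, (giant.three_ss + 200) % L))
        n, ev = detect_backsplice_support([("m", mrna_like)], giant, genome)
        assert n == 0 and ev[0].has_ligation and not ev[0].has_permuted_contiguity

    def test_permuted_precursor_alone_insufficient(self, study):
        genome, introns, pool = study["genome"], study["introns"], study["pool"]
        giant = introns[0]
        perm = next(e.species for e in pool
                    if e.species.species_class == SpeciesClass.PRECURSOR_PERMUTED)
        n, ev = detect_backsplice_support([("p", perm.sequence)], giant, genome)
        assert n == 0 and ev[0].has_permuted_contiguity and not ev[0].has_ligation
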