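"""Hairpin folding, precursor criteria, genome mapping, intron screening."""

import numpy as np
import pytest

from dcltools.hairpin import (
    PrecursorCriteria,
    evaluate_precursor,
    fold_window,
    locate_precursor,
    map_mature,
    nussinov_pair_table,
    screen_introns,
)
from dcltools.seqio import NucSeq, revcomp
from dcltools.simulate import SimConfig, make_genome

from conftest import random_nuc
from _oracles import brute_max_pairing

_WEIGHT = {("A", "T"): 2, ("T", "A"): 2, ("C", "G"): 2, ("G", "C"): 2,
           ("G", "T"): 1, ("T", "G"): 1}


def _total_weight(seq, pt):
    return sum(_WEIGHT[(seq[i], seq[j])] for i, j in enumerate(pt) if j > i)


class TestFold:
    def test_perfect_stem(self):
        hp = fold_window("GGGGAAAACCCC")
        assert hp.n_pairs == 4
        assert hp.loop == (4, 8)
        assert hp.seq[hp.loop[0]:hp.loop[1]] == "AAAA"
        assert hp.dot_bracket() == "((((....))))"

    def test_homopolymer_has_no_pairs(self):
        hp = fold_window("A" * 60)
        assert hp.n_pairs == 0

    @pytest.mark.parametrize("trial", range(60))
    def test_pairing_weight_matches_exhaustive(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(8, 15))
        seq = random_nuc(rng, n).seq
        pt = nussinov_pair_table(seq)
        assert _total_weight(seq, pt) == brute_max_pairing(seq)

    def test_pair_table_is_involution(self, rng):
        for _ in range(10):
            seq = random_nuc(rng, 80).seq
            pt = nussinov_pair_table(seq)
            for i, j in enumerate(pt):
                if j >= 0:
                    assert pt[j] == i

    def test_no_crossing_pairs(self, rng):
        seq = random_nuc(rng, 60).seq
        pt = nussinov_pair_table(seq)
        pairs = [(i, j) for i, j in enumerate(pt) if j > i]
        for a, b in pairs:
            for c, d in pairs:
                if a < c:
                    assert c > b or d < b  # nested or disjoint

    def test_min_loop_respected(self, rng):
        for _ in range(10):
            seq = random_nuc(rng, 40).seq
            pt = nussinov_pair_table(seq)
            for i, j in enumerate(pt):
                if j > i:
                    assert j - i > 3

    def test_short_window_raises(self):
        with pytest.raises(ValueError, match="too short"):
            fold_window("ACGTACGT")


class TestCriteria:
    def _perfect_hairpin(self, rng, arm=40, loop=8, mir_len=21):
        left = random_nuc(rng, arm).seq
        seq = left + random_nuc(rng, loop).seq + revcomp(left)
        return fold_window(seq), (5, 5 + mir_len)

    def test_perfect_inverted_repeat_passes(self, rng):
        hp, span = self._perfect_hairpin(rng)
        ev = evaluate_precursor(hp, span)
        assert ev.verdict
        assert ev.metrics["unpaired_mirna_nt"] == 0
        assert not ev.failure_reasons

    def test_excess_unpaired_mature_fails(self, rng):
        left = random_nuc(rng, 40).seq
        right = list(revcomp(left))
        # disrupt 5 partners of the mature span at positions 5..25
        for k in (6, 10, 14, 18, 22):
            i = 40 - 1 - k  # partner index within the 3' arm
            right[i] = {"A": "C", "C": "A", "G": "A", "T": "C"}[left[k]]
        seq = left + random_nuc(rng, 8).seq + "".join(right)
        hp = fold_window(seq)
        ev = evaluate_precursor(hp, (5, 26))
        assert ev.metrics["unpaired_mirna_nt"] >= 5
        assert not ev.checks["mismatches"]
        assert not ev.verdict
        assert any("unpaired" in r for r in ev.failure_reasons)

    def test_span_outside_window_raises(self, rng):
        hp, _ = self._perfect_hairpin(rng)
        with pytest.raises(ValueError, match="outside"):
            evaluate_precursor(hp, (80, 120))

    def test_shuffled_windows_rarely_pass(self):
        rng = np.random.default_rng(8)
        base = random_nuc(rng, 150).seq
        passes = 0
        for _ in range(100):
            # dinucleotide shuffle
            pairs = [base[i:i + 2] for i in range(0, len(base) - 1, 2)]
            rng.shuffle(pairs)
            seq = "".join(pairs)
            hp = fold_window(seq)
            ok = False
            for arm in (hp.arm5, hp.arm3):
                for s in range(arm[0], arm[1] - 21 + 1):
                    if evaluate_precursor(hp, (s, s + 21)).verdict:
                        ok = True
                        break
                if ok:
                    break
            passes += ok
        assert passes < 5


class TestMapping:
    def test_verbatim_plant_found_with_zero_mismatches(self, rng):
        mir = random_nuc(rng, 21, "mir")
        genome = NucSeq("chr", random_nuc(rng, 300).seq[:150] + mir.seq
                        + random_nuc(rng, 150).seq)
        hits = [h for h in map_mature(mir, [genome]) if h.mismatches == 0
                and h.strand == "+"]
        assert any(h.start == 150 for h in hits)

    def test_mismatch_threshold_is_sharp(self):
        rng = np.random.default_rng(17)
        mir = random_nuc(rng, 21, "mir")
        mutated = list(mir.seq)
        for i in (3, 9, 15):
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        two = "".join(mutated[:15]) + mir.seq[15:]  # only 2 of the 3 changes
        three = "".join(mutated)
        genome2 = NucSeq("chr", "T" * 60 + two + "T" * 60)
        genome3 = NucSeq("chr", "T" * 60 + three + "T" * 60)
        assert any(h.start == 60 for h in map_mature(mir, [genome2]))
        assert not any(h.start == 60 for h in map_mature(mir, [genome3]))

    def test_strand_symmetry(self, rng):
        mir = random_nuc(rng, 21, "mir")
        genome = random_nuc(rng, 400, "chr")
        flipped = NucSeq("chr", revcomp(genome.seq))
        fwd = map_mature(mir, [genome])
        rev = map_mature(mir, [flipped])
        n = len(genome)
        mirrored = sorted(
            (n - h.end, {"+": "-", "-": "+"}[h.strand], h.mismatches)
            for h in rev
        )
        assert sorted((h.start, h.strand, h.mismatches) for h in fwd) == mirrored

    def test_agreement_with_bruteforce_hamming(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            mir = random_nuc(rng, 18, "mir")
            genome = random_nuc(rng, 250, "chr")
            got = {(h.start, h.strand) for h in map_mature(mir, [genome], max_mm=2)}
            want = set()
            for strand, pat in (("+", mir.seq), ("-", revcomp(mir.seq))):
                for i in range(len(genome) - 18 + 1):
                    mm = sum(a != b for a, b in zip(genome.seq[i:i + 18], pat))
                    if mm <= 2:
                        want.add((i, strand))
            assert got == want


class TestPrecursorPipeline:
    def test_planted_mirs_recovered(self):
        sim = make_genome(SimConfig(seed=5, n_genes=2,
                                    exon_count_range=(3, 5),
                                    exon_len_range=(80, 150),
                                    intron_regime="compact"))
        assert sim.mirs
        for truth in sim.mirs:
            mir = NucSeq("m", truth.mature)
            evs = locate_precursor(mir, [sim.chrom])
            assert evs, f"planted {truth.placement} MIR not recovered"
            lo, hi = truth.locus
            assert any(
                ev.hit is not None and lo - 150 <= ev.hit.start <= hi + 150
                for ev in evs
            )

    def test_absent_mirna_yields_empty(self, rng):
        genome = random_nuc(rng, 800, "chr")
        mir = random_nuc(rng, 21, "mir")
        while mir.seq in genome.seq:
            mir = random_nuc(rng, 21, "mir")
        assert locate_precursor(mir, [genome]) == []

    def test_mapped_hit_without_hairpin_context_fails(self):
        rng = np.random.default_rng(23)
        mir = random_nuc(rng, 21, "mir")
        # homopolymer flanks cannot fold into any stem containing the mature
        genome = NucSeq("chr", "A" * 150 + mir.seq + "A" * 150)
        assert locate_precursor(mir, [genome]) == []

    def test_intron_screen_finds_planted_intronic_mir_only(self):
        sim = make_genome(SimConfig(seed=9, n_genes=2,
                                    exon_count_range=(3, 5),
                                    exon_len_range=(80, 150),
                                    intron_regime="compact",
                                    n_planted_mirs=2))
        intronic = [m for m in sim.mirs if m.placement == "intron"]
        assert intronic
        truth = intronic[0]
        gs = sim.structures[truth.gene_index]
        evs = screen_introns(gs, sim.chrom, mirna_len=21)
        assert evs
        assert any(
            ev.context.startswith(f"intron_{truth.intron_index + 1}:")
            for ev in evs
        )

    def test_unplanted_introns_are_clean(self):
        hits = 0
        for seed in range(10):
            sim = make_genome(SimConfig(seed=1000 + seed, n_genes=1,
                                        exon_count_range=(3, 5),
                                        exon_len_range=(80, 150),
                                        intron_regime="compact",
                                        n_planted_mirs=0))
            hits += len(screen_introns(sim.structures[0], sim.chrom))
        assert hits <= 1

    def test_intronless_gene_returns_empty(self, rng):
        from dcltools.genes import GeneStructure
        gs = GeneStructure(exons=((0, 500),))
        assert screen_introns(gs, random_nuc(rng, 500, "chr")) == []
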