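"""Duplex penalty alignment, scoring and transcript scanning."""

import numpy as np
import pytest

from dcltools.duplex import (
    BULGE_T,
    GU,
    MM,
    WC,
    Pair,
    PenaltyScheme,
    align_duplex,
    count_substitutions,
    scan_targets,
    score_duplex,
)
from dcltools.seqio import NucSeq, revcomp
from dcltools.simulate import SiteSpec, make_target_site

from conftest import random_nuc
from _oracles import brute_duplex_score


class TestScoreDuplex:
    def test_all_watson_crick_is_zero(self, scheme):
        pairs = [Pair(i, 21 - i, WC) for i in range(1, 22)]
        assert score_duplex(pairs, scheme) == 0.0

    def test_single_gu_outside_core(self, scheme):
        pairs = [Pair(i, 21 - i, GU if i == 18 else WC) for i in range(1, 22)]
        assert score_duplex(pairs, scheme) == 0.5

    def test_core_doubling(self, scheme):
        pairs = [Pair(i, 21 - i, MM if i == 5 else WC) for i in range(1, 22)]
        assert score_duplex(pairs, scheme) == 2.0

    def test_target_bulge_uses_five_prime_flank(self, scheme):
        # bulge between miRNA positions 15 and 16: non-core flank, 1.0
        pairs = [Pair(i, 0, WC) for i in range(1, 16)]
        pairs.append(Pair(None, 0, BULGE_T))
        pairs += [Pair(i, 0, WC) for i in range(16, 22)]
        assert score_duplex(pairs, scheme) == 1.0
        # bulge between positions 5 and 6: core flank, doubled
        pairs = [Pair(i, 0, WC) for i in range(1, 6)]
        pairs.append(Pair(None, 0, BULGE_T))
        pairs += [Pair(i, 0, WC) for i in range(6, 22)]
        assert score_duplex(pairs, scheme) == 2.0

    def test_unknown_state_raises(self, scheme):
        with pytest.raises(ValueError, match="unknown pair state"):
            score_duplex([Pair(1, 1, "XX")], scheme)


class TestAlignDuplex:
    def test_perfect_reverse_complement(self, scheme, rng):
        mir = random_nuc(rng, 21, "mir")
        dup = align_duplex(mir, NucSeq("w", revcomp(mir.seq)), scheme)
        assert dup.score == 0.0
        assert all(p.state == WC for p in dup.pairs)

    def test_single_inserted_target_nt_forces_bulge(self, scheme):
        mir = NucSeq("mir", "TCGATAAACCTCTGCATCCAG")
        w = revcomp(mir.seq)
        # insert a non-pairing nt opposite the non-core 15/16 flank
        idx = 21 - 15
        window = NucSeq("w", w[:idx] + "C" + w[idx:])
        dup = align_duplex(mir, window, scheme)
        assert dup.score == scheme.bulge_penalty_per_nt
        assert dup.n_bulged() == 1

    def test_window_too_short_raises(self, scheme, rng):
        mir = random_nuc(rng, 21, "mir")
        with pytest.raises(ValueError, match="shorter"):
            align_duplex(mir, NucSeq("w", "ACGTACGTACGTACGT"), scheme)

    @pytest.mark.parametrize("trial", range(200))
    def test_matches_bruteforce_enumeration(self, scheme, trial):
        rng = np.random.default_rng(1000 + trial)
        m_len = int(rng.integers(15, 23))
        w_len = int(rng.integers(m_len - 2, min(m_len + 2, 22) + 1))
        mir = random_nuc(rng, m_len, "mir")
        if rng.random() < 0.5:  # half the cases: corrupted near-complement
            w = list(revcomp(mir.seq))
            for _ in range(int(rng.integers(0, 4))):
                w[int(rng.integers(len(w)))] = "ACGT"[int(rng.integers(4))]
            window = NucSeq("w", "".join(w)[:w_len].ljust(w_len, "A"))
        else:
            window = random_nuc(rng, w_len, "w")
        got = align_duplex(mir, window, scheme).score
        want = brute_duplex_score(mir.seq, window.seq, scheme)
        assert got == pytest.approx(want)

    def test_adding_mismatch_never_decreases_score(self, scheme):
        rng = np.random.default_rng(7)
        for _ in range(30):
            mir = random_nuc(rng, 21, "mir")
            w = list(revcomp(mir.seq))
            base = align_duplex(mir, NucSeq("w", "".join(w)), scheme).score
            for _ in range(4):
                i = int(rng.integers(len(w)))
                w[i] = "ACGT"[int(rng.integers(4))]
                s = align_duplex(mir, NucSeq("w", "".join(w)), scheme).score
                assert s >= base
                base = s

    def test_score_equals_score_duplex_of_pairs(self, scheme, rng):
        mir = random_nuc(rng, 21, "mir")
        window = random_nuc(rng, 21, "w")
        dup = align_duplex(mir, window, scheme)
        assert dup.score == pytest.approx(score_duplex(dup.pairs, scheme))


class TestScan:
    def test_planted_perfect_site_found_at_zero(self, scheme):
        rng = np.random.default_rng(42)
        mir = random_nuc(rng, 21, "mir")
        bg = random_nuc(rng, 120, "t").seq
        site = revcomp(mir.seq)
        tr = NucSeq("t", bg[:50] + site + bg[50:])
        sites = scan_targets(mir, tr, scheme, cutoff=0.0)
        assert len(sites) == 1
        assert sites[0].score == 0.0
        assert sites[0].interval == (50, 71)

    def test_planted_composition_reports_analytic_score(self, scheme):
        # 2 non-core mismatches + 1 non-core bulged nt = 3.0
        n_exact = 0
        for seed in range(30):
            rng = np.random.default_rng(5000 + seed)
            mir = random_nuc(rng, 21, "mir")
            spec = SiteSpec(mm_noncore=2, bulge_noncore=1)
            window, expected = make_target_site(mir, spec, None, seed=rng)
            assert expected == 3.0
            bg = random_nuc(rng, 80, "t").seq
            at = 30
            tr = NucSeq("t", bg[:at] + window.seq + bg[at:])
            sites = scan_targets(mir, tr, scheme, cutoff=3.0)
            hit = [s for s in sites if s.interval[0] >= at - 2 and s.interval[1] <= at + len(window) + 2]
            assert hit and hit[0].score == pytest.approx(expected)
            n_exact += 1
        assert n_exact == 30

    def test_overlapping_hits_merged_keeping_best(self, scheme):
        rng = np.random.default_rng(9)
        mir = random_nuc(rng, 21, "mir")
        site = revcomp(mir.seq)
        tr = NucSeq("t", "ACGT" * 10 + site + "TGCA" * 10)
        sites = scan_targets(mir, tr, scheme, cutoff=5.0)
        ivals = [s.interval for s in sites]
        for i, a in enumerate(ivals):
            for b in ivals[i + 1:]:
                assert a[1] <= b[0] or b[1] <= a[0]  # disjoint after merge


class TestSubstitutions:
    def test_identical_sites(self):
        assert count_substitutions("ACGTACGT", "ACGTACGT") == 0

    def test_excluded_bulge_position(self):
        assert count_substitutions("AXCGT", "AYCGT", exclude={1}) == 0
        assert count_substitutions("ACGGT", "ATGAT", exclude={1}) == 1

    def test_unequal_after_exclusion_raises(self):
        with pytest.raises(ValueError, match="length"):
            count_substitutions("ACGTA", "ACGT")
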