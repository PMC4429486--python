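"""Cross-species site extraction, conservation reports, Fitch gain/loss."""

import dendropy
import numpy as np
import pytest

from dcltools.conservation import (
    OrthologSiteSet,
    build_report,
    build_site_set,
    extract_site,
    fitch_gain_loss,
)
from dcltools.duplex import PenaltyScheme
from dcltools.seqio import NucSeq, revcomp
from dcltools.simulate import SiteSpec, make_target_site
from dcltools.synthetic_panel import build_panel, embed_in_transcript

from conftest import random_nuc
from _oracles import brute_fitch_events


class TestExtractSite:
    def test_perfect_planted_site(self, scheme, rng):
        mir = random_nuc(rng, 21, "mir")
        site = revcomp(mir.seq)
        bg = random_nuc(rng, 140, "t").seq
        tr = NucSeq("t", bg[:60] + site + bg[60:])
        rec = extract_site(mir, tr, scheme)
        assert rec.score == 0.0
        assert rec.interval == (60, 81)

    def test_degraded_site_still_located(self, scheme):
        for seed in range(20):
            rng = np.random.default_rng(8800 + seed)
            mir = random_nuc(rng, 21, "mir")
            window, expected = make_target_site(
                mir, SiteSpec(mm_core=3, mm_noncore=2),
                scheme, seed=rng)
            tr, at = embed_in_transcript(window, seed=seed, length=200)
            rec = extract_site(mir, tr, scheme)
            assert rec.score == pytest.approx(expected)
            assert abs(rec.interval[0] - at) <= 2


class TestReport:
    def _panel_set(self, scheme):
        panel = build_panel()
        transcripts = {}
        for i, (name, w) in enumerate(panel.windows.items()):
            tr, _ = embed_in_transcript(w, seed=100 + i, length=160)
            transcripts[name] = tr
        return panel, build_site_set(panel.mirna, transcripts, "reference", scheme)

    def test_panel_statuses_and_substitutions(self, scheme):
        panel, sites = self._panel_set(scheme)
        report = build_report(sites, scheme, loss_threshold=4.0)
        t = report.table.set_index("species")
        assert t.loc["reference", "score"] == 1.0
        for profile in ("si_like", "oe_like", "rg_like"):
            assert t.loc[profile, "status"] == "retained"
        for profile in ("sm_like", "sel_like", "pp_like"):
            assert t.loc[profile, "status"] == "lost"
        for profile in panel.profiles:
            assert (t.loc[profile, "substitutions"]
                    == panel.planted_substitutions(profile))
        assert report.summary == {"retained": 5, "lost": 3}

    def test_report_permutation_invariant(self, scheme):
        _, sites = self._panel_set(scheme)
        rev = OrthologSiteSet(
            sites.mirna,
            dict(reversed(list(sites.sites.items()))),
            sites.reference_species,
        )
        a = build_report(sites, scheme).table
        b = build_report(rev, scheme).table
        assert a.equals(b)

    def test_missing_reference_raises(self, scheme):
        _, sites = self._panel_set(scheme)
        with pytest.raises(ValueError, match="reference"):
            OrthologSiteSet(sites.mirna, sites.sites, "nonexistent")

    def test_identical_sites_all_retained_zero_subs(self, scheme, rng):
        mir = random_nuc(rng, 21, "mir")
        site = revcomp(mir.seq)
        transcripts = {}
        for i, sp in enumerate(("a", "b", "c")):
            bg = random_nuc(rng, 120, sp).seq
            transcripts[sp] = NucSeq(sp, bg[:40] + site + bg[40:])
        report = build_report(
            build_site_set(mir, transcripts, "a", scheme), scheme)
        assert (report.table["status"] == "retained").all()
        assert (report.table["substitutions"] == 0).all()


class TestFitch:
    def test_all_present_no_events(self):
        glm = fitch_gain_loss("((A,B),(C,D));",
                              {x: "present" for x in "ABCD"})
        assert glm.n_events == 0

    def test_single_change(self):
        glm = fitch_gain_loss(
            "((A,B),(C,D));",
            {"A": "absent", "B": "absent", "C": "present", "D": "present"})
        assert glm.n_events == 1

    def test_missing_tip_raises(self):
        with pytest.raises(ValueError, match="state"):
            fitch_gain_loss("((A,B),(C,D));", {"A": "present"})

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_exhaustive_minimization(self, trial):
        rng = np.random.default_rng(4000 + trial)
        n = int(rng.integers(4, 11))
        taxa = [f"T{i}" for i in range(n)]
        # random binary topology by sequential joining
        groups = [t for t in taxa]
        while len(groups) > 1:
            i, j = sorted(rng.choice(len(groups), 2, replace=False))
            merged = f"({groups[i]},{groups[j]})"
            groups = [g for k, g in enumerate(groups) if k not in (i, j)]
            groups.append(merged)
        newick = groups[0] + ";"
        states = {t: ("present" if rng.random() < 0.5 else "absent")
                  for t in taxa}
        tree = dendropy.Tree.get(data=newick, schema="newick")
        want = brute_fitch_events(tree, states)
        got = fitch_gain_loss(newick, states)
        assert got.n_events == want
        assert len(got.events) == want

    def test_event_count_bounded_by_minority_state(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            taxa = [f"T{i}" for i in range(n)]
            groups = [t for t in taxa]
            while len(groups) > 1:
                i, j = sorted(rng.choice(len(groups), 2, replace=False))
                merged = f"({groups[i]},{groups[j]})"
                groups = [g for k, g in enumerate(groups) if k not in (i, j)]
                groups.append(merged)
            states = {t: ("present" if rng.random() < 0.5 else "absent")
                      for t in taxa}
            minority = min(
                sum(v == "present" for v in states.values()),
                sum(v == "absent" for v in states.values()),
            )
            glm = fitch_gain_loss(groups[0] + ";", states)
            assert glm.n_events <= minority

    def test_annotated_newick_contains_states(self):
        glm = fitch_gain_loss(
            "((A,B),(C,D));",
            {"A": "absent", "B": "absent", "C": "present", "D": "present"})
        out = glm.annotated_newick()
        assert "state" in out and "A" in out
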