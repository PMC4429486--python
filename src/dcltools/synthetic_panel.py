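"""SYNTHETIC stand-in panel for the cross-species miR162:DCL1 comparison.

The published comparison rests on a conserved ~21-nt miR162 complementary
site in DCL1 transcripts: a near-perfect duplex carrying one 1-nt target
bulge outside the scoring core (penalty 1.0 under the default scheme),
degraded in particular lineages by point substitutions. The deposited
transcript records themselves are not bundled here; instead this module
builds a *synthetic* panel whose per-species substitution compositions
reproduce the published pattern of site decay:

=============  =======================  =====  =============
profile        added substitutions      score  substitutions
=============  =======================  =====  =============
reference      none                     1.0    0
conserved      none                     1.0    0
si_like        1 core mismatch          3.0    1
oe_like        1 core mismatch          3.0    1
rg_like        2 non-core mismatches    3.0    2
sm_like        4 non-core mismatches    5.0    4
sel_like       3 core mismatches        7.0    3
pp_like        4 core mismatches        9.0    4
=============  =======================  =====  =============

Scores are what the duplex aligner computes from the raw windows; nothing
in this module scores anything itself. Substitution counts exclude the
bulged nucleotide. A separate helper builds a near-perfect miR397-style
site (1 core mismatch + 1 non-core mismatch + 1 non-core G:U = 3.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .duplex import PenaltyScheme
from .seqio import NucSeq, revcomp
from .simulate import SiteSpec, _non_pairing_base, _random_seq, make_target_site

#: miRNA positions substituted per species profile (1-based from the miRNA
#: 5' end; the default core window is 2-13). Chosen away from the bulge
#: flank and the duplex termini so the planted register is unambiguous.
PANEL_PROFILES: dict[str, tuple[int, ...]] = {
    "reference": (),
    "conserved": (),
    "si_like": (7,),
    "oe_like": (9,),
    "rg_like": (15, 18),
    "sm_like": (14, 15, 18, 19),
    "sel_like": (5, 8, 11),
    "pp_like": (4, 6, 10, 12),
}

#: Non-core miRNA flank of the single bulged target nucleotide.
BULGE_FLANK = 16


@dataclass(frozen=True)
class SitePanel:
    """Synthetic ortholog site windows plus the anchor miRNA."""

    mirna: NucSeq
    windows: dict[str, NucSeq]
    bulge_window_index: int
    profiles: dict[str, tuple[int, ...]]

    def planted_substitutions(self, profile: str) -> int:
        return len(self.profiles[profile])


def _window_index(mirna_pos: int, mirna_len: int, bulge_flank: int) -> int:
    """Window index facing a miRNA position, in the bulged window."""
    base = mirna_len - mirna_pos
    return base + (1 if mirna_pos <= bulge_flank else 0)


def profile_score(positions: tuple[int, ...],
                  scheme: PenaltyScheme | None = None) -> float:
    """Analytic panel score: the 1.0 bulge plus each substitution's cost."""
    scheme = scheme or PenaltyScheme()
    total = scheme.bulge_penalty_per_nt  # the non-core canonical bulge
    for p in positions:
        mult = scheme.core_multiplier if scheme.in_core(p) else 1.0
        total += scheme.mismatch_penalty * mult
    return total


def build_panel(seed: int = 20150513, mirna_len: int = 21) -> SitePanel:
    """Build the synthetic panel (deterministic for a given seed).

    The reference window is the exact reverse complement of a random
    21-mer with one non-pairing nucleotide inserted opposite miRNA
    positions 16/17 (the 3'-side, non-core bulge of the canonical site);
    each profile then substitutes non-pairing bases at its listed miRNA
    positions. Because point substitutions can occasionally open a cheaper
    alternative alignment for a particular miRNA sequence, the panel is
    verified against the aligner and scanner and redrawn until every
    profile scores exactly its analytic value.
    """
    from .duplex import align_duplex, scan_targets

    rng = np.random.default_rng(seed)
    scheme = PenaltyScheme()
    for _ in range(200):
        m = _random_seq(rng, mirna_len, 0.5)
        mirna = NucSeq("mir162_standin", m)
        ref = list(revcomp(m))
        bulge_idx = mirna_len - BULGE_FLANK
        ref.insert(bulge_idx,
                   _non_pairing_base(rng, m[BULGE_FLANK - 1], m[BULGE_FLANK]))
        windows: dict[str, NucSeq] = {}
        ok = True
        for profile, positions in PANEL_PROFILES.items():
            w = list(ref)
            for p in positions:
                w[_window_index(p, mirna_len, BULGE_FLANK)] = _non_pairing_base(
                    rng, m[p - 1], m[max(p - 2, 0)], m[min(p, mirna_len - 1)]
                )
            site = NucSeq(f"{profile}_DCL1_site", "".join(w))
            want = profile_score(positions, scheme)
            if abs(align_duplex(mirna, site, scheme).score - want) > 1e-9:
                ok = False
                break
            best_sub = min(s.score for s in
                           scan_targets(mirna, site, scheme, float("inf")))
            if abs(best_sub - want) > 1e-9:
                ok = False
                break
            windows[profile] = site
        if ok:
            return SitePanel(mirna, windows, bulge_idx, dict(PANEL_PROFILES))
    raise RuntimeError("could not realize a verified site panel")


def build_mir397_standin(
    seed: int = 397, mirna_len: int = 21, scheme: PenaltyScheme | None = None
) -> tuple[NucSeq, NucSeq, float]:
    """Near-perfect miR397-style site: 1 core MM + 1 non-core MM + 1 non-core G:U.

    Returns (mirna, window, analytic score); under the default scheme the
    analytic score is 3.5.
    """
    rng = np.random.default_rng(seed)
    spec = SiteSpec(mm_core=1, mm_noncore=1, gu_noncore=1)
    for _ in range(200):
        m = _random_seq(rng, mirna_len, 0.5)
        if not any(b in "GT" for b in m[13 : mirna_len - 3]):
            continue  # the wobble needs a non-core G/T position
        mirna = NucSeq("mir397_standin", m)
        try:
            window, expected = make_target_site(mirna, spec, scheme, seed=rng)
        except ValueError:
            continue
        return mirna, window, expected
    raise RuntimeError("could not realize a verified miR397-style site")


_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def _atg_free(rng: np.random.Generator, n: int) -> str:
    s = list(_random_seq(rng, n, 0.45))
    text = "".join(s)
    while "ATG" in text:
        i = text.index("ATG")
        s[i + 2] = "C"
        text = "".join(s)
    return text


def make_cdna_standin(
    seed: int,
    orf_bp: int,
    utr5_bp: int,
    utr3_bp: int,
    name: str = "cdna_standin",
) -> NucSeq:
    """SYNTHETIC cDNA with an exactly specified ORF/UTR architecture.

    The ORF is ATG + random non-stop codons + one stop; the UTRs are
    ATG-free, so the planted ORF is the unique longest one. Used as a
    stand-in for deposited transcript records whose tabulated features
    (ORF length, UTR lengths, deduced protein size) drive the checks.
    """
    if orf_bp % 3 != 0 or orf_bp < 6:
        raise ValueError("ORF length must be a positive multiple of 3")
    rng = np.random.default_rng(seed)
    n_codons = orf_bp // 3 - 2
    body = "".join(
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    )
    stop = ("TAA", "TAG", "TGA")[rng.integers(3)]
    return NucSeq(
        name, _atg_free(rng, utr5_bp) + "ATG" + body + stop + _atg_free(rng, utr3_bp)
    )


def make_gene_standin(
    cdna: NucSeq,
    n_introns: int,
    seed: int,
    intron_len_range: tuple[int, int] = (80, 400),
) -> tuple[NucSeq, tuple[tuple[int, int], ...]]:
    """SYNTHETIC genomic locus: the cDNA split by GT-AG introns.

    Returns the genomic sequence and the planted exon coordinates. Splice
    points leave every exon at least 20 nt.
    """
    rng = np.random.default_rng(seed)
    n = len(cdna)
    if n < (n_introns + 1) * 20:
        raise ValueError("cDNA too short for the requested intron count")
    while True:
        cuts = sorted(rng.choice(np.arange(20, n - 20), size=n_introns,
                                 replace=False).tolist())
        if all(b - a >= 20 for a, b in zip(cuts, cuts[1:])):
            break
    parts = []
    exons = []
    prev = 0
    gpos = 0
    for cut in cuts + [n]:
        exon = cdna.seq[prev:cut]
        parts.append(exon)
        exons.append((gpos, gpos + len(exon)))
        gpos += len(exon)
        if cut != n:
            ilen = int(rng.integers(*intron_len_range))
            intron = "GT" + _random_seq(rng, ilen - 4, 0.4) + "AG"
            parts.append(intron)
            gpos += len(intron)
        prev = cut
    return NucSeq(f"{cdna.id}_locus", "".join(parts)), tuple(exons)


def embed_in_transcript(
    window: NucSeq,
    seed: int,
    length: int = 300,
    at: int | None = None,
) -> tuple[NucSeq, int]:
    """Plant a site window inside a random transcript background."""
    rng = np.random.default_rng(seed)
    bg = _random_seq(rng, length, 0.45)
    if at is None:
        at = int(rng.integers(30, length - len(window) - 30))
    seq = bg[:at] + window.seq + bg[at + len(window):]
    return NucSeq(f"{window.id}_transcript", seq), at
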