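"""miRNA:target duplex construction and mismatch penalty scoring.

A plant miRNA target site is judged by an additive penalty over the duplex
formed between the mature miRNA and a ~20-base window of the transcript:
each mismatch costs 1.0, each G:U wobble 0.5, each bulged nucleotide 1.0,
and penalties are doubled when they fall opposite the miRNA "core"
(positions 2-13 from the miRNA 5' end). Lower scores mean better targets;
a perfect Watson-Crick duplex scores 0.0.

Everything is computed on the DNA alphabet (U normalized to T), so a G:U
wobble is G(miRNA):T(target) or T(miRNA):G(target).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .seqio import NucSeq, revcomp

WC = "WC"
GU = "GU"
MM = "MM"
BULGE_T = "BULGE_T"  # unpaired target nucleotide
BULGE_M = "BULGE_M"  # unpaired miRNA nucleotide

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PenaltyScheme:
    """Scoring constants for duplex imperfections.

    Defaults follow the common plant-target convention: mismatch 1.0,
    G:U 0.5, 1.0 per bulged nucleotide, all doubled in the core window
    (miRNA positions 2-13, 1-based from the 5' end), at most 2 bulged
    nucleotides per duplex.
    """

    mismatch_penalty: float = 1.0
    gu_penalty: float = 0.5
    bulge_penalty_per_nt: float = 1.0
    core_range: tuple[int, int] = (2, 13)
    core_multiplier: float = 2.0
    max_bulged_nt: int = 2
    window_nt: int = 20

    def __post_init__(self) -> None:
        if min(self.mismatch_penalty, self.gu_penalty,
               self.bulge_penalty_per_nt) < 0:
            raise ValueError("penalties must be non-negative")

    def in_core(self, mirna_pos: int) -> bool:
        lo, hi = self.core_range
        return lo <= mirna_pos <= hi


@dataclass(frozen=True)
class Pair:
    """One rung of the duplex ladder.

    ``mirna_pos`` is 1-based from the miRNA 5' end (None for a bulged
    target nt); ``target_pos`` indexes the target window 5'->3' (None for
    a bulged miRNA nt).
    """

    mirna_pos: int | None
    target_pos: int | None
    state: str


@dataclass(frozen=True)
class Duplex:
    mirna_id: str
    target_id: str
    target_interval: tuple[int, int]
    pairs: tuple[Pair, ...]
    score: float

    def n_bulged(self) -> int:
        return sum(p.state in (BULGE_T, BULGE_M) for p in self.pairs)

    def mirna_to_target_base(self, mirna: str, window: str) -> dict[int, str]:
        """Map each miRNA position to the target base facing it ('-' if bulged)."""
        out: dict[int, str] = {}
        for p in self.pairs:
            if p.mirna_pos is not None:
                out[p.mirna_pos] = (
                    window[p.target_pos] if p.target_pos is not None else "-"
                )
        return out

    def render(self, mirna: str, window: str) -> str:
        """Three-line text rendering: target 5'->3' over miRNA 3'->5'.

        '|' marks Watson-Crick pairs, 'o' G:U wobbles, ' ' mismatches;
        bulged nucleotides face a gap '-' on the opposite strand.
        """
        top, mid, bot = [], [], []
        for p in reversed(self.pairs):  # target left-to-right
            t = window[p.target_pos] if p.target_pos is not None else "-"
            m = mirna[p.mirna_pos - 1] if p.mirna_pos is not None else "-"
            top.append(t)
            bot.append(m)
            mid.append({WC: "|", GU: "o"}.get(p.state, " "))
        return (
            f"5' {''.join(top)} 3'  {self.target_id}\n"
            f"   {''.join(mid)}\n"
            f"3' {''.join(bot)} 5'  {self.mirna_id}"
        )


@dataclass(frozen=True)
class TargetSite:
    transcript_id: str
    interval: tuple[int, int]
    score: float
    duplex: Duplex


def classify_pair(m: str, t: str) -> str:
    if _COMP.get(m) == t:
        return WC
    if (m == "G" and t == "T") or (m == "T" and t == "G"):
        return GU
    return MM


def pair_penalty(state: str, mirna_pos: int, scheme: PenaltyScheme) -> float:
    """Penalty of one duplex rung given its governing miRNA position.

    For bulges the governing position is the flanking miRNA position nearer
    the 5' end (target bulges) or the bulged position itself (miRNA bulges).
    """
    if state == WC:
        base = 0.0
    elif state == GU:
        base = scheme.gu_penalty
    elif state == MM:
        base = scheme.mismatch_penalty
    elif state in (BULGE_T, BULGE_M):
        base = scheme.bulge_penalty_per_nt
    else:
        raise ValueError(f"unknown pair state {state!r}")
    if base and scheme.in_core(mirna_pos):
        base *= scheme.core_multiplier
    return base


def score_duplex(pairs: Sequence[Pair], scheme: PenaltyScheme) -> float:
    """Additive penalty of a pair list (ordered miRNA 5'->3')."""
    total = 0.0
    last_mirna_pos = 0
    for p in pairs:
        if p.state == BULGE_T:
            pos = last_mirna_pos  # flank nearer the miRNA 5' end
        else:
            pos = p.mirna_pos
            last_mirna_pos = p.mirna_pos
        total += pair_penalty(p.state, max(pos, 1), scheme)
    return total


# ---------------------------------------------------------------------------
# optimal duplex by dynamic programming

def _dp_tables(m: str, t: str, scheme: PenaltyScheme):
    """Forward DP over (miRNA prefix i, reversed-target prefix j, bulges b).

    ``t`` is the target window already reversed, so miRNA position i pairs
    colinearly with t[j]. Cell values are (score, n_bulged, tie) tuples;
    ``tie`` prefers bulges nearer the miRNA 3' end.
    """
    M, T = len(m), len(t)
    B = scheme.max_bulged_nt
    INF = (float("inf"), 0, 0)
    D = [[[INF] * (B + 1) for _ in range(T + 1)] for _ in range(M + 1)]
    D[0][0][0] = (0.0, 0, 0)
    for i in range(M + 1):
        for j in range(T + 1):
            for b in range(B + 1):
                cur = D[i][j][b]
                if cur[0] == float("inf"):
                    continue
                sc, nb, tie = cur
                if i < M and j < T:  # pair miRNA i+1 with t[j]
                    state = classify_pair(m[i], t[j])
                    cand = (sc + pair_penalty(state, i + 1, scheme), nb, tie)
                    if cand < D[i + 1][j + 1][b]:
                        D[i + 1][j + 1][b] = cand
                if b < B:
                    if i < M:  # bulge the miRNA nt i+1
                        cand = (
                            sc + pair_penalty(BULGE_M, i + 1, scheme),
                            nb + 1,
                            tie + (M - (i + 1)),
                        )
                        if cand < D[i + 1][j][b + 1]:
                            D[i + 1][j][b + 1] = cand
                    if j < T:  # bulge the target nt t[j]; 5' flank = miRNA pos i
                        cand = (
                            sc + pair_penalty(BULGE_T, max(i, 1), scheme),
                            nb + 1,
                            tie + (M - max(i, 1)),
                        )
                        if cand < D[i][j + 1][b + 1]:
                            D[i][j + 1][b + 1] = cand
    return D


def _traceback(m: str, t: str, scheme: PenaltyScheme, D, j_end: int):
    B = scheme.max_bulged_nt
    M = len(m)
    b = min(range(B + 1), key=lambda bb: D[M][j_end][bb])
    i, j = M, j_end
    pairs: list[Pair] = []
    while i > 0 or j > 0:
        cur = D[i][j][b]
        placed = False
        if i > 0 and j > 0:
            state = classify_pair(m[i - 1], t[j - 1])
            prev = D[i - 1][j - 1][b]
            if prev[0] != float("inf"):
                cand = (prev[0] + pair_penalty(state, i, scheme), prev[1], prev[2])
                if cand == cur:
                    pairs.append(Pair(i, j - 1, state))
                    i, j = i - 1, j - 1
                    placed = True
        if not placed and i > 0 and b > 0:
            prev = D[i - 1][j][b - 1]
            if prev[0] != float("inf"):
                cand = (
                    prev[0] + pair_penalty(BULGE_M, i, scheme),
                    prev[1] + 1,
                    prev[2] + (M - i),
                )
                if cand == cur:
                    pairs.append(Pair(i, None, BULGE_M))
                    i, b = i - 1, b - 1
                    placed = True
        if not placed and j > 0 and b > 0:
            prev = D[i][j - 1][b - 1]
            if prev[0] != float("inf"):
                cand = (
                    prev[0] + pair_penalty(BULGE_T, max(i, 1), scheme),
                    prev[1] + 1,
                    prev[2] + (M - max(i, 1)),
                )
                if cand == cur:
                    pairs.append(Pair(None, j - 1, BULGE_T))
                    j, b = j - 1, b - 1
                    placed = True
        if not placed:
            raise AssertionError("duplex traceback failed")
    pairs.reverse()
    return pairs


def _window_pairs_to_target_coords(pairs: list[Pair], window_len: int) -> tuple[Pair, ...]:
    """Convert reversed-target indices back to window 5'->3' positions."""
    return tuple(
        Pair(p.mirna_pos,
             None if p.target_pos is None else window_len - 1 - p.target_pos,
             p.state)
        for p in pairs
    )


def align_duplex(mirna: NucSeq, window: NucSeq, scheme: PenaltyScheme | None = None) -> Duplex:
    """Minimum-penalty duplex of a mature miRNA against a target window.

    The window is given 5'->3' in transcript orientation; the miRNA binds
    antiparallel. At most ``scheme.max_bulged_nt`` nucleotides may be bulged
    on either strand in total. Ties are resolved toward fewer bulged
    nucleotides, then bulges closest to the miRNA 3' end.
    """
    scheme = scheme or PenaltyScheme()
    M, W = len(mirna), len(window)
    if not 15 <= M <= 30:
        raise ValueError("mature miRNA must be 15-30 nt")
    if W < M - scheme.max_bulged_nt:
        raise ValueError(
            f"window of {W} nt is shorter than miRNA length minus the "
            f"allowed bulges ({M - scheme.max_bulged_nt} nt)"
        )
    # window_nt counts paired target nucleotides; physically the window may
    # carry up to max_bulged_nt extra (bulged) bases, and a miRNA longer
    # than window_nt widens the cap accordingly
    if W > max(scheme.window_nt, M) + scheme.max_bulged_nt:
        raise ValueError("window exceeds the scoring window size")
    t = window.seq[::-1]
    D = _dp_tables(mirna.seq, t, scheme)
    pairs = _traceback(mirna.seq, t, scheme, D, W)
    pairs = _window_pairs_to_target_coords(pairs, W)
    score = score_duplex(pairs, scheme)
    return Duplex(mirna.id, window.id, (0, W), pairs, score)


def scan_targets(
    mirna: NucSeq,
    transcript: NucSeq,
    scheme: PenaltyScheme | None = None,
    cutoff: float = 4.0,
) -> list[TargetSite]:
    """Scan a transcript for candidate target sites.

    Every window position is scored by the optimal-duplex aligner (window
    lengths within ``max_bulged_nt`` of the miRNA length); overlapping hits
    are merged keeping the best score. Sites scoring at most ``cutoff`` are
    returned sorted by score, then position.
    """
    scheme = scheme or PenaltyScheme()
    M = len(mirna)
    B = scheme.max_bulged_nt
    n = len(transcript)
    if n < M - B:
        raise ValueError("transcript shorter than the scoring window")
    m = mirna.seq
    raw: list[tuple[int, int, float]] = []
    lmax = min(M + B, max(scheme.window_nt, M) + B)
    # one DP per window *end*: all window lengths share the reversed prefix
    for e in range(M - B, n + 1):
        t = transcript.seq[max(0, e - lmax):e][::-1]
        D = _dp_tables(m, t, scheme)
        best_len, best = None, None
        for ell in range(M - B, min(lmax, len(t)) + 1):
            cell = min(D[M][ell], key=lambda c: c)
            if cell[0] == float("inf"):
                continue
            if best is None or (cell[0], ell) < (best[0], best_len):
                best, best_len = cell, ell
        if best is not None:
            raw.append((e - best_len, e, best[0]))
    # merge overlapping candidate windows, keep the best-scoring one
    raw.sort(key=lambda r: (r[0], r[1]))
    merged: list[tuple[int, int, float]] = []
    cluster: list[tuple[int, int, float]] = []
    cluster_end = -1
    for r in raw:
        if cluster and r[0] >= cluster_end:
            merged.append(min(cluster, key=lambda c: (c[2], c[0])))
            cluster = []
        cluster.append(r)
        cluster_end = max(cluster_end, r[1])
    if cluster:
        merged.append(min(cluster, key=lambda c: (c[2], c[0])))
    sites: list[TargetSite] = []
    for start, end, score in merged:
        if score > cutoff:
            continue
        window = transcript.subseq(start, end)
        dup = align_duplex(mirna, window, scheme)
        dup = replace(dup, target_id=transcript.id, target_interval=(start, end))
        sites.append(TargetSite(transcript.id, (start, end), dup.score, dup))
    sites.sort(key=lambda s: (s.score, s.interval))
    return sites


def count_substitutions(
    site: str | NucSeq,
    reference_site: str | NucSeq,
    exclude: Iterable[int] = (),
) -> int:
    """Hamming count between two pre-aligned site windows.

    ``exclude`` lists 0-based positions (e.g. the bulged nucleotide) removed
    from both sequences before comparison; the remainders must be equal
    length.
    """
    s = site.seq if isinstance(site, NucSeq) else site
    r = reference_site.seq if isinstance(reference_site, NucSeq) else reference_site
    excl = set(exclude)
    s2 = "".join(c for i, c in enumerate(s) if i not in excl)
    r2 = "".join(c for i, c in enumerate(r) if i not in excl)
    if len(s2) != len(r2):
        raise ValueError(
            f"sites differ in length after exclusions ({len(s2)} vs {len(r2)})"
        )
    return sum(a != b for a, b in zip(s2, r2))


def report_sites(sites: Sequence[TargetSite], mirna: NucSeq,
                 transcript: NucSeq) -> str:
    """TSV site report with the three-line duplex rendering inlined."""
    lines = ["#transcript_id\tstart\tend\tscore\tduplex"]
    for s in sites:
        window = transcript.seq[s.interval[0]:s.interval[1]]
        rendered = s.duplex.render(mirna.seq, window).replace("\n", "; ")
        lines.append(
            f"{s.transcript_id}\t{s.interval[0]}\t{s.interval[1]}\t"
            f"{s.score:g}\t{rendered}"
        )
    return "\n".join(lines) + "\n"
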