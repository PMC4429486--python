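"""miRNA precursor validation: genome mapping, hairpin folding, criteria.

A mature miRNA is credited with a precursor when it maps onto the genome
(Hamming distance <= 2 by default), the surrounding genomic window folds
into a stem-loop, and the stem-loop satisfies community annotation
criteria: the mature sequence lies in one arm of a single stem, pairs well
with its star region, and the duplex is not grossly asymmetric.

Folding uses a weighted maximum-pairing (Nussinov-style) dynamic program
(Watson-Crick pairs weight 2, G:U wobbles 1, minimum loop 3 nt). The
folder is a pluggable backend: any callable mapping a sequence to a pair
table can be substituted for the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genes import GeneStructure
from .seqio import NucSeq, revcomp

MIN_LOOP = 3

_PAIR_WEIGHT = {
    ("A", "T"): 2, ("T", "A"): 2,
    ("C", "G"): 2, ("G", "C"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}


@dataclass(frozen=True)
class GenomeHit:
    chrom: str
    start: int
    strand: str
    mismatches: int
    length: int

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class Hairpin:
    """A folded window reduced to its best single stem-loop."""

    seq: str
    pair_table: list[int]  # partner index, or -1 when unpaired
    arm5: tuple[int, int]
    arm3: tuple[int, int]
    loop: tuple[int, int]
    n_pairs: int

    def dot_bracket(self) -> str:
        out = []
        for i, j in enumerate(self.pair_table):
            out.append("." if j < 0 else ("(" if j > i else ")"))
        return "".join(out)


@dataclass(frozen=True)
class PrecursorCriteria:
    """Operational thresholds for plant MIR annotation."""

    max_mirna_mismatches: int = 4
    max_asymmetric_bulge_nt: int = 2
    min_paired_fraction_mirna: float = 0.75
    mirna_in_single_arm: bool = True
    #: the mature:star duplex must be a near-contiguous helix: at most this
    #: many distinct unpaired runs inside the mature span (the operational
    #: form of "no large internal loops or bulges")
    max_duplex_interruptions: int = 2
    #: precursor-scale stem: the best stem-loop must carry at least this
    #: many base pairs, so the mature:star duplex is embedded in a longer
    #: helix as in real pre-miRNAs (and short chance stems of a
    #: pairing-maximizing fold do not qualify)
    min_stem_pairs: int = 25


@dataclass
class PrecursorEvaluation:
    hairpin: Hairpin
    mirna_span: tuple[int, int]
    checks: dict[str, bool]
    metrics: dict[str, float]
    verdict: bool
    failure_reasons: list[str]
    hit: GenomeHit | None = None
    context: str = ""


# ---------------------------------------------------------------------------
# mapping

def _hamming_hits(pattern: str, text: str, max_mm: int) -> list[tuple[int, int]]:
    k, n = len(pattern), len(text)
    if n < k:
        return []
    arr = np.frombuffer(text.encode(), dtype=np.uint8)
    pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    mism = (windows != pat).sum(axis=1)
    return [(int(i), int(m)) for i, m in enumerate(mism) if m <= max_mm]


def map_mature(
    mirna: NucSeq,
    genome: Sequence[NucSeq],
    max_mm: int = 2,
) -> list[GenomeHit]:
    """Exhaustive Hamming mapping of a mature miRNA on both genome strands."""
    if not 15 <= len(mirna) <= 30:
        raise ValueError("mature miRNA must be 15-30 nt")
    hits: list[GenomeHit] = []
    rc = revcomp(mirna.seq)
    for chrom in genome:
        for pos, mm in _hamming_hits(mirna.seq, chrom.seq, max_mm):
            hits.append(GenomeHit(chrom.id, pos, "+", mm, len(mirna)))
        for pos, mm in _hamming_hits(rc, chrom.seq, max_mm):
            hits.append(GenomeHit(chrom.id, pos, "-", mm, len(mirna)))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# folding

def _fill_scores_loops(w: np.ndarray, min_loop: int) -> np.ndarray:
    """O(n^3) Nussinov fill with explicit loops (numba-jitted when available)."""
    n = w.shape[0]
    W = np.zeros((n, n), dtype=np.int32)
    for l in range(1, n):
        for i in range(n - l):
            j = i + l
            best = W[i + 1, j] if W[i + 1, j] > W[i, j - 1] else W[i, j - 1]
            if l > min_loop and w[i, j] > 0:
                cand = W[i + 1, j - 1] + w[i, j]
                if cand > best:
                    best = cand
            for k in range(i + 1, j - 1):
                cand = W[i, k] + W[k + 1, j]
                if cand > best:
                    best = cand
            W[i, j] = best
    return W


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _fill_scores_loops = njit(cache=False)(_fill_scores_loops)
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _fill_scores_numpy(w: np.ndarray, min_loop: int) -> np.ndarray:
    """Diagonal-vectorized Nussinov fill (fallback without numba)."""
    n = w.shape[0]
    D = [np.zeros(n - l, dtype=np.int32) for l in range(n)]
    for l in range(1, n):
        cur = np.maximum(D[l - 1][1:], D[l - 1][:-1])  # i or j unpaired
        if l > min_loop:
            pair_w = np.diagonal(w, offset=l).astype(np.int32)
            inner = D[l - 2][1:-1]
            cur = np.maximum(cur, np.where(pair_w > 0, inner + pair_w, -1))
        for d in range(1, l - 1):  # bifurcation with both sides non-trivial
            cur = np.maximum(cur, D[d][: n - l] + D[l - d - 1][d + 1 : n - l + d + 1])
        D[l] = cur
    W = np.zeros((n, n), dtype=np.int32)
    for l in range(1, n):
        for i in range(n - l):
            W[i, i + l] = D[l][i]
    return W


def nussinov_pair_table(seq: str, min_loop: int = MIN_LOOP) -> list[int]:
    """Maximum-weight non-crossing pairing (WC=2, G:U=1).

    Deterministic traceback preferring the outermost compatible pair.
    """
    n = len(seq)
    if n == 0:
        return []
    w = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(n):
            w[i, j] = _PAIR_WEIGHT.get((seq[i], seq[j]), 0)
    fill = _fill_scores_loops if _HAVE_NUMBA else _fill_scores_numpy
    W = fill(w, min_loop)
    pt = [-1] * n

    def score(i: int, j: int) -> int:
        return 0 if j <= i else int(W[i, j])

    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        s = score(i, j)
        if s == 0:
            continue
        if w[i, j] > 0 and s == score(i + 1, j - 1) + w[i, j]:
            pt[i], pt[j] = j, i
            stack.append((i + 1, j - 1))
        elif s == score(i + 1, j):
            stack.append((i + 1, j))
        elif s == score(i, j - 1):
            stack.append((i, j - 1))
        else:
            for k in range(i + 1, j):
                if s == score(i, k) + score(k + 1, j):
                    stack.append((i, k))
                    stack.append((k + 1, j))
                    break
            else:  # pragma: no cover
                raise AssertionError("fold traceback failed")
    return pt


FoldBackend = Callable[[str], list[int]]


def _stem_loops(pt: list[int]) -> list[tuple[list[tuple[int, int]], tuple[int, int]]]:
    """Decompose a pair table into stems, each ending in a hairpin loop.

    Returns (pairs-on-stem, loop interval) per stem; a stem is a maximal
    chain of nested pairs uninterrupted by a multiloop branch.
    """
    pairs = sorted((i, j) for i, j in enumerate(pt) if j > i)
    if not pairs:
        return []
    # children: pairs immediately nested inside a pair
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in pairs}
    roots: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p in pairs:
        while stack and not (stack[-1][0] < p[0] and p[1] < stack[-1][1]):
            stack.pop()
        if stack:
            children[stack[-1]].append(p)
        else:
            roots.append(p)
        stack.append(p)
    # a stem follows the heaviest branch through multiloops (small side
    # branches become unpaired interruptions of the reported stem-loop);
    # each side branch is also a candidate stem start of its own
    chain_memo: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def chain_from(p: tuple[int, int]) -> list[tuple[int, int]]:
        if p not in chain_memo:
            kids = children[p]
            if not kids:
                chain_memo[p] = [p]
            else:
                best = max(kids, key=lambda k: (len(chain_from(k)), -k[0]))
                chain_memo[p] = [p] + chain_from(best)
        return chain_memo[p]

    starts = list(roots)
    for p in pairs:
        if len(children[p]) > 1:
            starts.extend(children[p])
    stems = []
    for s in starts:
        chain = chain_from(s)
        inner = chain[-1]
        stems.append((chain, (inner[0] + 1, inner[1])))
    return stems


def fold_window(
    seq: NucSeq | str,
    min_loop: int = MIN_LOOP,
    backend: FoldBackend | None = None,
) -> Hairpin:
    """Fold a window and return its best single stem-loop.

    The best stem-loop is the one carrying the most base pairs (leftmost on
    ties); positions outside it are reported unpaired.
    """
    s = seq.seq if isinstance(seq, NucSeq) else seq
    if len(s) < 12:
        raise ValueError("window too short to fold (need >= 12 nt)")
    pt = (backend or (lambda x: nussinov_pair_table(x, min_loop)))(s)
    stems = _stem_loops(pt)
    if not stems:
        return Hairpin(s, [-1] * len(s), (0, 0), (0, 0), (0, len(s)), 0)
    chain, loop = max(stems, key=lambda st: (len(st[0]), -st[0][0][0]))
    keep = set()
    for i, j in chain:
        keep.add(i)
        keep.add(j)
    pt2 = [pt[i] if i in keep else -1 for i in range(len(s))]
    lefts = sorted(i for i, _ in chain)
    rights = sorted(j for _, j in chain)
    return Hairpin(
        seq=s,
        pair_table=pt2,
        arm5=(lefts[0], lefts[-1] + 1),
        arm3=(rights[0], rights[-1] + 1),
        loop=loop,
        n_pairs=len(chain),
    )


# ---------------------------------------------------------------------------
# criteria

def evaluate_precursor(
    hairpin: Hairpin,
    mirna_span: tuple[int, int],
    criteria: PrecursorCriteria | None = None,
) -> PrecursorEvaluation:
    """Judge a candidate precursor against annotation criteria.

    Checks: (i) mature miRNA entirely within one arm; (ii) at most
    ``max_mirna_mismatches`` unpaired mature nucleotides; (iii) mature/star
    asymmetry at most ``max_asymmetric_bulge_nt``; (iv) paired fraction of
    the mature at least ``min_paired_fraction_mirna``. The verdict is the
    conjunction, and every verdict records the numbers it compared.
    """
    c = criteria or PrecursorCriteria()
    a, b = mirna_span
    n = len(hairpin.seq)
    if not (0 <= a < b <= n):
        raise ValueError(f"mature span {mirna_span} outside window of {n} nt")
    span_len = b - a
    pt = hairpin.pair_table
    in5 = hairpin.arm5[0] <= a and b <= hairpin.arm5[1]
    in3 = hairpin.arm3[0] <= a and b <= hairpin.arm3[1]
    single_arm = in5 or in3

    paired = [i for i in range(a, b) if pt[i] >= 0]
    unpaired = span_len - len(paired)
    paired_frac = len(paired) / span_len

    def gap_runs(lo: int, hi: int) -> int:
        runs, in_gap = 0, False
        for i in range(lo, hi):
            if pt[i] < 0:
                if not in_gap:
                    runs += 1
                in_gap = True
            else:
                in_gap = False
        return runs

    interruptions = gap_runs(a, b)
    if paired:
        star_lo = min(pt[i] for i in paired)
        star_hi = max(pt[i] for i in paired) + 1
        # the duplex must be clean on both strands
        interruptions = max(interruptions, gap_runs(star_lo, star_hi))
    if paired:
        partners = [pt[i] for i in paired]
        star_len = max(partners) - min(partners) + 1
        asymmetry = abs(star_len - span_len)
    else:
        asymmetry = float("inf")

    checks = {
        "single_arm": single_arm or not c.mirna_in_single_arm,
        "mismatches": unpaired <= c.max_mirna_mismatches,
        "asymmetry": asymmetry <= c.max_asymmetric_bulge_nt,
        "paired_fraction": paired_frac >= c.min_paired_fraction_mirna,
        "duplex_contiguity": interruptions <= c.max_duplex_interruptions,
        "stem_size": hairpin.n_pairs >= c.min_stem_pairs,
    }
    metrics = {
        "unpaired_mirna_nt": unpaired,
        "asymmetry_nt": asymmetry,
        "paired_fraction": round(paired_frac, 3),
        "duplex_interruptions": interruptions,
        "stem_pairs": hairpin.n_pairs,
    }
    reasons = []
    if not checks["single_arm"]:
        reasons.append("mature miRNA not contained in a single hairpin arm")
    if not checks["mismatches"]:
        reasons.append(
            f"{unpaired} unpaired mature nt exceeds {c.max_mirna_mismatches}")
    if not checks["asymmetry"]:
        reasons.append(
            f"mature/star asymmetry {asymmetry} nt exceeds "
            f"{c.max_asymmetric_bulge_nt}")
    if not checks["paired_fraction"]:
        reasons.append(
            f"paired fraction {paired_frac:.2f} below "
            f"{c.min_paired_fraction_mirna}")
    if not checks["duplex_contiguity"]:
        reasons.append(
            f"{interruptions} unpaired runs in the mature span exceed "
            f"{c.max_duplex_interruptions}")
    if not checks["stem_size"]:
        reasons.append(
            f"stem of {hairpin.n_pairs} pairs below precursor scale "
            f"({c.min_stem_pairs})")
    return PrecursorEvaluation(
        hairpin=hairpin,
        mirna_span=mirna_span,
        checks=checks,
        metrics=metrics,
        verdict=all(checks.values()),
        failure_reasons=reasons,
    )


def _window_candidates(region: str, mirna_len: int,
                       criteria: PrecursorCriteria,
                       backend: FoldBackend | None) -> PrecursorEvaluation | None:
    """Best passing mature-candidate evaluation in one folded window."""
    try:
        hp = fold_window(region, backend=backend)
    except ValueError:
        return None
    best: PrecursorEvaluation | None = None
    for arm in (hp.arm5, hp.arm3):
        lo, hi = arm
        if hi - lo < mirna_len:
            continue
        for s in range(lo, hi - mirna_len + 1):
            ev = evaluate_precursor(hp, (s, s + mirna_len), criteria)
            if ev.verdict and (
                best is None
                or ev.metrics["unpaired_mirna_nt"] < best.metrics["unpaired_mirna_nt"]
            ):
                best = ev
    return best


def screen_introns(
    gs: GeneStructure,
    genomic: NucSeq,
    criteria: PrecursorCriteria | None = None,
    mirna_len: int = 21,
    window: int = 300,
    step: int = 150,
    backend: FoldBackend | None = None,
) -> list[PrecursorEvaluation]:
    """Screen every intron of a gene for an embedded MIR-like stem-loop.

    Long introns are folded in sliding windows; a pass in any window counts
    for the intron. An empty list means no intron harbours a candidate.
    """
    c = criteria or PrecursorCriteria()
    out: list[PrecursorEvaluation] = []
    for idx, (a, b) in enumerate(gs.introns):
        if b - a < 40:
            continue
        found: PrecursorEvaluation | None = None
        starts = range(a, max(a + 1, b - window + 1), step) if b - a > window else [a]
        for s in starts:
            region = genomic.seq[s : min(s + window, b)]
            if len(region) < 40:
                continue
            ev = _window_candidates(region, mirna_len, c, backend)
            if ev is not None:
                ev.context = f"intron_{idx + 1}:{s}-{min(s + window, b)}"
                found = ev
                break
        if found is not None:
            out.append(found)
    return out


def locate_precursor(
    mirna: NucSeq,
    genome: Sequence[NucSeq],
    flank: int = 150,
    criteria: PrecursorCriteria | None = None,
    max_mm: int = 2,
    backend: FoldBackend | None = None,
) -> list[PrecursorEvaluation]:
    """Map a mature miRNA and test each locus for a plausible precursor.

    Pipeline: Hamming mapping -> +-flank window extraction -> stem-loop
    folding -> criteria evaluation. Only passing evaluations are returned;
    an empty list mirrors an absent miRNA.
    """
    c = criteria or PrecursorCriteria()
    genome_by_id = {g.id: g for g in genome}
    passing: list[PrecursorEvaluation] = []
    for hit in map_mature(mirna, genome, max_mm=max_mm):
        chrom = genome_by_id[hit.chrom]
        lo = max(0, hit.start - flank)
        hi = min(len(chrom), hit.end + flank)
        region = chrom.seq[lo:hi]
        if hit.strand == "-":
            region = revcomp(region)
            span = (hi - hit.end, hi - hit.start)
        else:
            span = (hit.start - lo, hit.end - lo)
        try:
            hp = fold_window(region, backend=backend)
        except ValueError:
            continue
        ev = evaluate_precursor(hp, span, c)
        ev.hit = hit
        ev.context = f"{hit.chrom}:{lo}-{hi}({hit.strand})"
        if ev.verdict:
            passing.append(ev)
    return passing


def verdict_report(evals: Sequence[PrecursorEvaluation]) -> str:
    """TSV verdict report, one evaluated locus per line."""
    lines = ["#context\tverdict\tunpaired_mirna_nt\tasymmetry_nt\t"
             "paired_fraction\tstem_pairs\treasons\tstructure"]
    for ev in evals:
        lines.append(
            f"{ev.context}\t{'pass' if ev.verdict else 'fail'}\t"
            f"{ev.metrics['unpaired_mirna_nt']}\t{ev.metrics['asymmetry_nt']}\t"
            f"{ev.metrics['paired_fraction']}\t{ev.metrics['stem_pairs']}\t"
            f"{';'.join(ev.failure_reasons) or '-'}\t{ev.hairpin.dot_bracket()}"
        )
    return "\n".join(lines) + "\n"
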