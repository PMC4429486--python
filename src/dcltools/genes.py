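"""Gene-level characterization of cloned cDNAs.

Covers the sequence features typically tabulated for a plant gene family:
longest ORF, deduced protein with molecular weight and theoretical pI,
5'/3' UTR partitioning, and exon/intron structure inferred by exact spliced
alignment of the cDNA against its genomic locus (GT-AG introns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .seqio import NucSeq, revcomp

# ---------------------------------------------------------------------------
# proteins

#: Average residue masses in Da (monomer minus water).
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153

#: EMBOSS pKa set. Side chains D,E,C,Y are acidic; H,K,R basic.
EMBOSS_PKA: dict[str, float] = {
    "Nterm": 8.6, "Cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,
    "H": 6.5, "K": 10.8, "R": 12.5,
}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


def protein_mw(residues: str) -> float:
    """Average-isotopic molecular weight in Da (residue masses + one water)."""
    if not residues:
        raise ValueError("empty protein")
    try:
        total = sum(AVERAGE_RESIDUE_MASS[aa] for aa in residues)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return total + WATER_MASS


def _net_charge(residues: str, ph: float, pka: Mapping[str, float]) -> float:
    pos = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    for aa in _BASIC:
        n = residues.count(aa)
        if n:
            pos += n / (1.0 + 10 ** (ph - pka[aa]))
    neg = 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for aa in _ACIDIC:
        n = residues.count(aa)
        if n:
            neg += n / (1.0 + 10 ** (pka[aa] - ph))
    return pos - neg


def protein_pi(residues: str, pka: Mapping[str, float] | None = None) -> float:
    """Theoretical isoelectric point.

    The pH at which the Henderson-Hasselbalch net charge over D,E,C,Y,H,K,R
    plus the two termini crosses zero, found by bisection. The pKa table
    defaults to the EMBOSS set and is configurable.
    """
    if not residues:
        raise ValueError("empty protein")
    pka = dict(pka or EMBOSS_PKA)
    lo, hi = 0.0, 14.0
    for _ in range(60):
        mid = (lo + hi) / 2.0
        if _net_charge(residues, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 2)


@dataclass(frozen=True)
class ProteinSeq:
    """Deduced protein with its bulk physicochemical descriptors."""

    residues: str

    @property
    def length_aa(self) -> int:
        return len(self.residues)

    @property
    def mw_da(self) -> float:
        return protein_mw(self.residues)

    @property
    def pi(self) -> float:
        return protein_pi(self.residues)


# ---------------------------------------------------------------------------
# ORFs

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Orf:
    """An ATG..stop open reading frame on the forward strand.

    ``length_bp`` includes the stop codon, so the deduced protein has
    ``length_bp/3 - 1`` residues.
    """

    start: int
    end: int
    strand: str = "+"

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def find_longest_orf(seq: NucSeq, all_frames: bool = False) -> Orf | None:
    """Longest complete ORF in the three forward frames.

    Ties are broken by the 5'-most start. Returns ``None`` when no
    ATG-to-stop frame exists (an explicit no-ORF result). ``all_frames``
    additionally searches the reverse strand (off by default: cloned cDNAs
    are sense-strand).
    """
    if len(seq) < 6:
        raise ValueError("sequence shorter than 6 nt cannot contain an ORF")
    best = _scan_forward(seq.seq)
    if all_frames:
        rc_best = _scan_forward(revcomp(seq.seq))
        if rc_best is not None and (
            best is None or rc_best.length_bp > best.length_bp
        ):
            n = len(seq)
            best = Orf(n - rc_best.end, n - rc_best.start, strand="-")
    return best


def _scan_forward(s: str) -> Orf | None:
    best: Orf | None = None
    n = len(s)
    for frame in range(3):
        open_start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = s[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    cand = Orf(open_start, pos + 3)
                    if (
                        best is None
                        or cand.length_bp > best.length_bp
                        or (cand.length_bp == best.length_bp and cand.start < best.start)
                    ):
                        best = cand
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = pos
    return best


def translate(seq: NucSeq, orf: Orf) -> ProteinSeq:
    """Translate an ORF with the standard genetic code, dropping the stop."""
    cds = seq.seq[orf.start : orf.end]
    if len(cds) % 3 != 0:
        raise ValueError("ORF length not divisible by 3")
    aa = str(Seq(cds).translate())
    if not aa.endswith("*"):
        raise ValueError("ORF does not end in a stop codon")
    body = aa[:-1]
    if "*" in body:
        offset = orf.start + body.index("*") * 3
        raise ValueError(f"internal stop codon at offset {offset}")
    return ProteinSeq(body)


def utr_partition(cdna: NucSeq, orf: Orf) -> tuple[int, int]:
    """(5'UTR bp, 3'UTR bp) flanking an ORF located within the cDNA."""
    if orf.start < 0 or orf.end > len(cdna):
        raise ValueError("ORF not contained in cDNA")
    return orf.start, len(cdna) - orf.end


# ---------------------------------------------------------------------------
# spliced gene structure


class SplicedAlignmentError(ValueError):
    """The cDNA cannot be represented as a GT-AG spliced substring."""


@dataclass(frozen=True)
class GeneStructure:
    """Exon chain of a gene on its genomic sequence (0-based half-open)."""

    exons: tuple[tuple[int, int], ...]
    utr5_bp: int = 0
    utr3_bp: int = 0
    noncanonical: bool = False

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    def splice(self, genomic: NucSeq) -> str:
        return "".join(genomic.seq[a:b] for a, b in self.exons)


def infer_gene_structure(
    cdna: NucSeq,
    genomic: NucSeq,
    min_intron: int = 20,
    min_exon_seed: int = 15,
) -> GeneStructure:
    """Exact-match spliced alignment of a cDNA onto its genomic locus.

    Finds an exon chain whose concatenation reproduces the cDNA
    byte-for-byte, with every intron at least ``min_intron`` nt and flanked
    by the canonical GT..AG dinucleotides. Exon seeds anchor at
    ``min_exon_seed`` exact nucleotides. Among alternative chains the
    5'-most splice donor wins at each junction.
    """
    c, g = cdna.seq, genomic.seq
    n = len(c)
    seed = min(min_exon_seed, n)
    first = c[:seed]

    start = g.find(first)
    starts = []
    while start != -1:
        starts.append(start)
        start = g.find(first, start + 1)
    if not starts:
        raise SplicedAlignmentError(
            f"5' end of cDNA ({first!r}) not found in genomic sequence"
        )

    deepest = [0]  # furthest cDNA offset reached, for error reporting

    def match_len(ci: int, gi: int) -> int:
        k = 0
        while ci + k < n and gi + k < len(g) and c[ci + k] == g[gi + k]:
            k += 1
        return k

    def search(ci: int, gi: int, exons: list[tuple[int, int]]):
        k = match_len(ci, gi)
        deepest[0] = max(deepest[0], ci + k)
        if ci + k == n:
            return exons + [(gi, gi + k)]
        # the current exon ends somewhere in [1, k]; try 5'-most donors first
        for s in range(1, k + 1):
            donor = gi + s
            if g[donor : donor + 2] != "GT":
                continue
            want = c[ci + s : ci + s + min(seed, n - ci - s)]
            if not want:
                continue
            acc = g.find(want, donor + min_intron)
            while acc != -1:
                if g[acc - 2 : acc] == "AG":
                    res = search(ci + s, acc, exons + [(gi, donor)])
                    if res is not None:
                        return res
                acc = g.find(want, acc + 1)
        return None

    for st in starts:
        result = search(0, st, [])
        if result is not None:
            gs = GeneStructure(exons=tuple(result))
            assert gs.splice(genomic) == c  # contract
            return gs
    raise SplicedAlignmentError(
        f"cDNA block starting at offset {deepest[0]} cannot be mapped "
        "onto the genomic sequence with GT-AG introns"
    )


# ---------------------------------------------------------------------------
# reporting

def transcript_to_genomic(gs: GeneStructure, start: int, end: int) -> list[tuple[int, int]]:
    """Project a transcript interval through the exon chain."""
    out: list[tuple[int, int]] = []
    off = 0
    for a, b in gs.exons:
        exon_len = b - a
        lo, hi = max(start, off), min(end, off + exon_len)
        if lo < hi:
            out.append((a + lo - off, a + hi - off))
        off += exon_len
    return out


def write_gff3(
    gs: GeneStructure,
    chrom: str,
    gene_id: str,
    path: str | Path,
    orf: Orf | None = None,
) -> None:
    """Emit gene/mRNA/exon (+UTR) records, converting to 1-based inclusive."""
    lines = ["##gff-version 3"]
    gstart, gend = gs.exons[0][0], gs.exons[-1][1]

    def rec(ftype: str, a: int, b: int, attrs: str) -> str:
        return f"{chrom}\tdcltools\t{ftype}\t{a + 1}\t{b}\t.\t+\t.\t{attrs}"

    lines.append(rec("gene", gstart, gend, f"ID={gene_id}"))
    lines.append(rec("mRNA", gstart, gend, f"ID={gene_id}.1;Parent={gene_id}"))
    for i, (a, b) in enumerate(gs.exons, 1):
        lines.append(rec("exon", a, b, f"ID={gene_id}.1.exon{i};Parent={gene_id}.1"))
    if orf is not None:
        tlen = sum(b - a for a, b in gs.exons)
        for a, b in transcript_to_genomic(gs, 0, orf.start):
            lines.append(rec("five_prime_UTR", a, b, f"Parent={gene_id}.1"))
        for a, b in transcript_to_genomic(gs, orf.end, tlen):
            lines.append(rec("three_prime_UTR", a, b, f"Parent={gene_id}.1"))
    Path(path).write_text("\n".join(lines) + "\n")


def characterize(cdna: NucSeq, genomic: NucSeq | None = None) -> dict:
    """Sequence-feature row for one cDNA: ORF, UTRs, protein, MW, pI, introns."""
    orf = find_longest_orf(cdna)
    row: dict = {"id": cdna.id, "length_bp": len(cdna)}
    if orf is None:
        row.update(orf_bp=0, utr5_bp=None, utr3_bp=None,
                   protein_aa=None, mw_kda=None, pi=None)
    else:
        prot = translate(cdna, orf)
        utr5, utr3 = utr_partition(cdna, orf)
        row.update(
            orf_bp=orf.length_bp,
            utr5_bp=utr5,
            utr3_bp=utr3,
            protein_aa=prot.length_aa,
            mw_kda=round(prot.mw_da / 1000.0, 1),
            pi=prot.pi,
        )
    if genomic is not None:
        row["intron_count"] = infer_gene_structure(cdna, genomic).intron_count
    return row
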