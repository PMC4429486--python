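"""Nucleotide sequence container and file I/O.

All sequences are held on the DNA alphabet: input U residues are normalized
to T on read, case is folded to upper. Coordinates are 0-based half-open
throughout the package; writers that emit 1-based formats (GFF3) convert on
write.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_ALLOWED = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize(residues: str) -> str:
    """Fold to upper case and map U -> T."""
    return residues.upper().replace("U", "T")


@dataclass(frozen=True)
class NucSeq:
    """A named linear nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize(self.seq))
        if not self.seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.seq) - _ALLOWED
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-nucleotide characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def __getitem__(self, key) -> str:
        return self.seq[key]

    def subseq(self, start: int, end: int, id: str | None = None) -> "NucSeq":
        return NucSeq(id or f"{self.id}:{start}-{end}", self.seq[start:end])

    def revcomp(self, id: str | None = None) -> "NucSeq":
        return NucSeq(id or f"{self.id}_rc", revcomp(self.seq))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[NucSeq]:
    return [NucSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_genbank(path: str | Path) -> list[NucSeq]:
    """Read GenBank flat files; the record sequence is returned as-is.

    CDS features, when present, are exposed through :func:`read_genbank_cds`.
    """
    return [NucSeq(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "genbank")]


def read_genbank_cds(path: str | Path) -> dict[str, tuple[int, int]]:
    """Return {record id: (cds_start, cds_end)} for records annotating a CDS.

    Coordinates are 0-based half-open on the record sequence.
    """
    out: dict[str, tuple[int, int]] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type == "CDS":
                out[rec.id] = (int(feat.location.start), int(feat.location.end))
                break
    return out


def read_sequences(path: str | Path) -> list[NucSeq]:
    """Dispatch FASTA vs GenBank on content sniffing."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("LOCUS"):
        return read_genbank(path)
    return read_fasta(path)


def write_fasta(seqs: Iterable[NucSeq], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


def iter_kmers(seq: str, k: int) -> Iterator[tuple[int, str]]:
    for i in range(len(seq) - k + 1):
        yield i, seq[i : i + k]
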