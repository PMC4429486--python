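"""Seeded generators for every input class the pipeline consumes.

These stand in for an unassembled genome: multi-exon genes with GT-AG
introns (with a configurable intron-size inflation regime mimicking
intron-enlarged gene families), planted MIR stem-loops (intergenic and
intronic), miRNA target sites of specified mismatch/G:U/bulge composition,
protein families with planted clades, and Cq tables with known fold
changes. Every generator is a pure function of its config and seed, and
each emits machine-readable ground truth sufficient for downstream checks.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .duplex import PenaltyScheme
from .genes import GeneStructure
from .phylo import MultipleAlignment
from .seqio import NucSeq, revcomp, write_fasta

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_GU_PARTNER = {"G": "T", "T": "G"}
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.42) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


# ---------------------------------------------------------------------------
# target sites


@dataclass(frozen=True)
class SiteSpec:
    """Composition of imperfections to plant into a target window.

    Counts are split by whether the governing miRNA position falls in the
    scoring core; bulges are single bulged target nucleotides.
    """

    mm_core: int = 0
    mm_noncore: int = 0
    gu_core: int = 0
    gu_noncore: int = 0
    bulge_core: int = 0
    bulge_noncore: int = 0

    def expected_score(self, scheme: PenaltyScheme) -> float:
        k = scheme.core_multiplier
        return (
            self.mm_core * scheme.mismatch_penalty * k
            + self.mm_noncore * scheme.mismatch_penalty
            + self.gu_core * scheme.gu_penalty * k
            + self.gu_noncore * scheme.gu_penalty
            + self.bulge_core * scheme.bulge_penalty_per_nt * k
            + self.bulge_noncore * scheme.bulge_penalty_per_nt
        )


def _non_pairing_base(rng: np.random.Generator, *mirna_bases: str) -> str:
    banned = set()
    for b in mirna_bases:
        banned.add(_COMP[b])
        if b in _GU_PARTNER:
            banned.add(_GU_PARTNER[b])
    options = [b for b in "ACGT" if b not in banned]
    if not options:
        primary = {_COMP[mirna_bases[0]]}
        if mirna_bases[0] in _GU_PARTNER:
            primary.add(_GU_PARTNER[mirna_bases[0]])
        options = [b for b in "ACGT" if b not in primary]
    return options[rng.integers(len(options))]


def make_target_site(
    mirna: NucSeq,
    spec: SiteSpec,
    scheme: PenaltyScheme | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[NucSeq, float]:
    """Build a target window realizing ``spec`` against ``mirna``.

    Starts from the exact reverse complement and introduces exactly the
    requested mismatches, wobbles and bulged nucleotides at core/non-core
    positions. Terminal miRNA positions are left untouched so the planted
    register is unambiguous. Returns the window and the analytic score.
    """
    scheme = scheme or PenaltyScheme()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = mirna.seq
    M = len(m)
    # positions within 3 nt of either duplex end stay untouched, so the
    # planted register is anchored by perfect pairs and a scanning window
    # cannot truncate a planted penalty away for less than it costs
    lo, hi = scheme.core_range
    core_pool = [p for p in range(max(4, lo), min(hi, M - 3) + 1)]
    noncore_pool = [p for p in range(4, M - 2) if p not in range(lo, hi + 1)]
    expected = spec.expected_score(scheme)

    def build() -> str:
        core, noncore = list(core_pool), list(noncore_pool)
        window = list(revcomp(m))  # window index M - i faces miRNA position i

        def take(pool: list[int], k: int, pred=lambda p: True) -> list[int]:
            avail = [p for p in pool if pred(p)]
            if len(avail) < k:
                raise ValueError(
                    "site spec requires more positions than available")
            picked = sorted(rng.choice(avail, size=k, replace=False).tolist())
            for p in picked:
                pool.remove(p)
            return picked

        for p in take(core, spec.mm_core) + take(noncore, spec.mm_noncore):
            # avoid bases that could pair after a 1-nt register shift
            window[M - p] = _non_pairing_base(rng, m[p - 1], m[p - 2], m[p])
        for p in take(core, spec.gu_core, lambda p: m[p - 1] in _GU_PARTNER) + take(
            noncore, spec.gu_noncore, lambda p: m[p - 1] in _GU_PARTNER
        ):
            window[M - p] = _GU_PARTNER[m[p - 1]]
        # bulges: insert between the bases facing miRNA positions p and p+1
        # (the 5'-nearer flank p governs the core multiplier)
        inner = lambda p: p <= M - 4
        flanks = take(core, spec.bulge_core, inner) + take(
            noncore, spec.bulge_noncore, inner)
        for p in sorted(flanks):  # 3'-most flank = smallest window index
            window.insert(M - p, _non_pairing_base(rng, m[p - 1], m[p]))
        return "".join(window)

    # rejection sampling: dense compositions can admit a cheaper alternative
    # alignment (a repositioned bulge, or a truncated sub-window absorbing
    # the planted bulge into a register shift); redraw positions until the
    # planted register is optimal over the full window and every sub-window,
    # so the emitted truth is exact for both aligner and scanner
    from .duplex import align_duplex, scan_targets

    last_err: ValueError | None = None
    for _ in range(60):
        try:
            w = build()
        except ValueError as exc:
            # may be transient: e.g. mismatch draws consumed the only G/T
            # positions a wobble needed; redraw
            last_err = exc
            continue
        site = NucSeq(f"{mirna.id}_site", w)
        if abs(align_duplex(mirna, site, scheme).score - expected) > 1e-9:
            continue
        best_sub = min(
            s.score for s in scan_targets(mirna, site, scheme, cutoff=float("inf"))
        )
        if abs(best_sub - expected) < 1e-9:
            return site, expected
    raise last_err or ValueError(
        f"could not realize spec {spec} as an optimal planted site for "
        f"{mirna.id}"
    )


# ---------------------------------------------------------------------------
# genomes


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Defaults emulate a five-member DCL-like family: genes of 19-24 introns,
    an intron-size inflation regime (log-normal, enlarged median 400 nt vs
    compact 100 nt), ~42% GC background, and three planted 21-nt MIR
    stem-loops alternating between intergenic space and introns.
    """

    seed: int
    n_genes: int = 5
    exon_count_range: tuple[int, int] = (20, 25)
    exon_len_range: tuple[int, int] = (80, 300)
    intron_regime: str = "enlarged"  # or "compact"
    intron_median: dict = field(
        default_factory=lambda: {"compact": 100.0, "enlarged": 400.0}
    )
    intron_sigma: float = 0.6
    min_intron: int = 60
    gc_content: float = 0.42
    intergenic_len_range: tuple[int, int] = (300, 1200)
    n_planted_mirs: int = 3
    mir_len: int = 21
    mir_arm: int = 60
    mir_loop: int = 9
    mir_imperfections: int = 2
    target_site_specs: tuple[SiteSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for a, b in (self.exon_count_range, self.exon_len_range,
                     self.intergenic_len_range):
            if a > b or a < 1:
                raise ValueError("ranges must be ordered and positive")
        if self.intron_regime not in self.intron_median:
            raise ValueError(f"unknown intron regime {self.intron_regime!r}")


@dataclass
class PlantedMir:
    mature: str
    locus: tuple[int, int]  # hairpin interval on the chromosome
    mature_span: tuple[int, int]
    placement: str  # "intergenic" or "intron"
    gene_index: int | None = None
    intron_index: int | None = None


@dataclass
class PlantedSite:
    gene_index: int
    cdna_interval: tuple[int, int]
    mirna: str
    spec: SiteSpec
    expected_score: float


@dataclass
class GenomeSim:
    """A synthetic chromosome with full ground truth."""

    config: SimConfig
    chrom: NucSeq
    cdnas: list[NucSeq]
    structures: list[GeneStructure]
    mirs: list[PlantedMir]
    sites: list[PlantedSite]

    def truth_dict(self) -> dict:
        return {
            "config": {
                **{k: v for k, v in asdict(self.config).items()
                   if k != "target_site_specs"},
                "target_site_specs": [asdict(s) for s in self.config.target_site_specs],
            },
            "genes": [
                {
                    "cdna_id": c.id,
                    "exons": list(map(list, gs.exons)),
                    "intron_count": gs.intron_count,
                }
                for c, gs in zip(self.cdnas, self.structures)
            ],
            "mirs": [asdict(m) for m in self.mirs],
            "sites": [asdict(s) for s in self.sites],
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([self.chrom], outdir / "genome.fa")
        write_fasta(self.cdnas, outdir / "cdnas.fa")
        if self.mirs:
            write_fasta(
                [NucSeq(f"mir{i + 1}", m.mature) for i, m in enumerate(self.mirs)],
                outdir / "mirnas.fa",
            )
        lines = ["##gff-version 3"]
        for gi, gs in enumerate(self.structures):
            gid = f"gene{gi + 1}"
            a, b = gs.exons[0][0], gs.exons[-1][1]
            lines.append(f"{self.chrom.id}\tdcltools\tgene\t{a + 1}\t{b}\t.\t+\t.\tID={gid}")
            for ei, (x, y) in enumerate(gs.exons, 1):
                lines.append(
                    f"{self.chrom.id}\tdcltools\texon\t{x + 1}\t{y}\t.\t+\t.\t"
                    f"ID={gid}.exon{ei};Parent={gid}"
                )
        (outdir / "genes.gff3").write_text("\n".join(lines) + "\n")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth_dict(), indent=1, sort_keys=True) + "\n"
        )


def _make_hairpin(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, str, int]:
    """(hairpin sequence, mature sequence, mature offset in hairpin)."""
    arm5 = _random_seq(rng, cfg.mir_arm, cfg.gc_content)
    mature_off = int(rng.integers(2, cfg.mir_arm - cfg.mir_len - 2))
    mature = arm5[mature_off : mature_off + cfg.mir_len]
    loop = _random_seq(rng, cfg.mir_loop, cfg.gc_content)
    arm3 = list(revcomp(arm5))
    # imperfections opposite non-mature arm positions keep the mature fully paired
    safe = [
        i for i in range(cfg.mir_arm)
        if not (mature_off <= cfg.mir_arm - 1 - i < mature_off + cfg.mir_len)
    ]
    for i in rng.choice(safe, size=min(cfg.mir_imperfections, len(safe)),
                        replace=False):
        arm3[int(i)] = _non_pairing_base(rng, arm5[cfg.mir_arm - 1 - int(i)])
    return arm5 + loop + "".join(arm3), mature, mature_off


def make_genome(cfg: SimConfig) -> GenomeSim:
    """Generate one chromosome of multi-exon genes with planted features.

    Genes are on the forward strand; every intron starts GT and ends AG.
    cDNAs equal the spliced exon chains byte-for-byte. MIR hairpins are
    planted as imperfect inverted repeats; target sites are spliced into
    exons so they appear in both cDNA and genome.
    """
    rng = np.random.default_rng(cfg.seed)
    median = cfg.intron_median[cfg.intron_regime]

    def intron_len() -> int:
        return max(cfg.min_intron,
                   int(rng.lognormal(np.log(median), cfg.intron_sigma)))

    # pre-build MIR hairpins and decide placements
    mirs: list[PlantedMir] = []
    hairpins: list[tuple[str, str, int, str]] = []
    for k in range(cfg.n_planted_mirs):
        hp, mature, moff = _make_hairpin(rng, cfg)
        placement = "intergenic" if k % 2 == 0 else "intron"
        hairpins.append((hp, mature, moff, placement))

    # per-gene exon/intron material, with target sites planted into exons
    genes: list[dict] = []
    site_truth: list[PlantedSite] = []
    specs = list(cfg.target_site_specs)
    for gi in range(cfg.n_genes):
        n_exons = int(rng.integers(cfg.exon_count_range[0],
                                   cfg.exon_count_range[1] + 1))
        exons = [
            _random_seq(rng, int(rng.integers(cfg.exon_len_range[0],
                                              cfg.exon_len_range[1] + 1)),
                        cfg.gc_content)
            for _ in range(n_exons)
        ]
        if specs:  # one planted site per gene while specs remain
            spec = specs.pop(0)
            mirna = NucSeq(f"simmir_g{gi + 1}", _random_seq(rng, cfg.mir_len, 0.5))
            site, exp = make_target_site(mirna, spec, seed=rng)
            ei = int(rng.integers(0, n_exons))
            exon = exons[ei]
            off = int(rng.integers(5, len(exon) - len(site) - 5))
            exons[ei] = exon[:off] + site.seq + exon[off + len(site):]
            cdna_off = sum(len(e) for e in exons[:ei]) + off
            site_truth.append(
                PlantedSite(gi, (cdna_off, cdna_off + len(site)),
                            mirna.seq, spec, exp)
            )
        introns = []
        for _ in range(n_exons - 1):
            body = _random_seq(rng, max(intron_len() - 4, cfg.min_intron - 4),
                               cfg.gc_content)
            introns.append("GT" + body + "AG")
        genes.append({"exons": exons, "introns": introns})

    # place intronic hairpins
    intronic = [h for h in hairpins if h[3] == "intron"]
    for k, (hp, mature, moff, _) in enumerate(intronic):
        gi = k % cfg.n_genes
        introns = genes[gi]["introns"]
        if not introns:
            continue
        ii = int(rng.integers(0, len(introns)))
        body = introns[ii][2:-2]
        if len(body) < len(hp) + 40:
            body = body + _random_seq(rng, len(hp) + 40 - len(body), cfg.gc_content)
        pos = int(rng.integers(20, len(body) - len(hp) - 19))
        introns[ii] = "GT" + body[:pos] + hp + body[pos + len(hp):] + "AG"
        genes[gi]["mir_intron"] = (ii, pos + 2, hp, mature, moff)

    # assemble the chromosome
    chrom_parts: list[str] = []
    pos = 0
    cdnas: list[NucSeq] = []
    structures: list[GeneStructure] = []
    intergenic_queue = [h for h in hairpins if h[3] == "intergenic"]

    def emit_intergenic() -> None:
        nonlocal pos
        gap = int(rng.integers(*cfg.intergenic_len_range))
        seq = _random_seq(rng, gap, cfg.gc_content)
        if intergenic_queue:
            hp, mature, moff, _ = intergenic_queue.pop(0)
            at = int(rng.integers(20, max(21, gap - len(hp) - 20)))
            seq = seq[:at] + hp + seq[at + len(hp):]
            if len(seq) < gap:
                seq = seq + _random_seq(rng, gap - len(seq), cfg.gc_content)
            mirs.append(
                PlantedMir(mature, (pos + at, pos + at + len(hp)),
                           (pos + at + moff, pos + at + moff + len(mature)),
                           "intergenic")
            )
        chrom_parts.append(seq)
        pos += len(seq)

    for gi, gene in enumerate(genes):
        emit_intergenic()
        exon_coords: list[tuple[int, int]] = []
        for i, exon in enumerate(gene["exons"]):
            exon_coords.append((pos, pos + len(exon)))
            chrom_parts.append(exon)
            pos += len(exon)
            if i < len(gene["introns"]):
                intr = gene["introns"][i]
                if "mir_intron" in gene and gene["mir_intron"][0] == i:
                    ii, at, hp, mature, moff = gene["mir_intron"]
                    mirs.append(
                        PlantedMir(mature, (pos + at, pos + at + len(hp)),
                                   (pos + at + moff, pos + at + moff + len(mature)),
                                   "intron", gene_index=gi, intron_index=i)
                    )
                chrom_parts.append(intr)
                pos += len(intr)
        cdna = "".join(gene["exons"])
        cdnas.append(NucSeq(f"cdna{gi + 1}", cdna))
        structures.append(GeneStructure(exons=tuple(exon_coords)))
    emit_intergenic()

    chrom = NucSeq("chr1", "".join(chrom_parts))
    for gs, cd in zip(structures, cdnas):
        assert gs.splice(chrom) == cd.seq  # emitted truth is self-consistent
    return GenomeSim(cfg, chrom, cdnas, structures, mirs, site_truth)


# ---------------------------------------------------------------------------
# protein families


@dataclass
class FamilyConfig:
    """Planted-clade protein family, defaults mirroring a 17-member,
    four-clade DCL census (5+4+4+4 tips)."""

    seed: int
    clade_sizes: tuple[int, ...] = (5, 4, 4, 4)
    length: int = 300
    between_divergence: float = 0.5
    within_divergence: float = 0.05


def _mutate_protein(rng: np.random.Generator, seq: np.ndarray,
                    rate: float) -> np.ndarray:
    out = seq.copy()
    k = int(round(rate * len(seq)))
    if k == 0:
        return out
    posns = rng.choice(len(seq), size=k, replace=False)
    for p in posns:
        choices = _AA[_AA != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return out


def make_protein_family(cfg: FamilyConfig) -> tuple[MultipleAlignment, dict[str, list[str]]]:
    """Aligned protein family with planted clades and its clade truth."""
    if len(cfg.clade_sizes) < 2:
        raise ValueError("need at least two clades")
    rng = np.random.default_rng(cfg.seed)
    ancestor = _AA[rng.integers(0, len(_AA), size=cfg.length)]
    ids: list[str] = []
    rows: list[str] = []
    truth: dict[str, list[str]] = {}
    for ci, size in enumerate(cfg.clade_sizes, 1):
        clade_anc = _mutate_protein(rng, ancestor, cfg.between_divergence)
        members = []
        for ti in range(1, size + 1):
            tip = _mutate_protein(rng, clade_anc, cfg.within_divergence)
            name = f"clade{ci}_t{ti}"
            ids.append(name)
            rows.append("".join(tip))
            members.append(name)
        truth[f"clade{ci}"] = members
    return MultipleAlignment(tuple(ids), tuple(rows)), truth


# ---------------------------------------------------------------------------
# Cq tables


@dataclass
class CqConfig:
    """Synthetic qPCR design: five DCL-like targets, a flat reference gene,
    four tissues with the calibrator fold fixed at 1, Gaussian Cq noise."""

    seed: int
    samples: tuple[str, ...] = ("root", "stem", "leaf", "flower")
    calibrator: str = "root"
    ref_gene: str = "UBQ"
    true_folds: dict = field(
        default_factory=lambda: {
            "DCL1": {"root": 1.0, "stem": 0.4, "leaf": 0.9, "flower": 3.0},
            "DCL2": {"root": 1.0, "stem": 0.3, "leaf": 0.25, "flower": 0.5},
            "DCL3": {"root": 1.0, "stem": 0.9, "leaf": 1.1, "flower": 1.0},
            "DCL4a": {"root": 1.0, "stem": 0.3, "leaf": 0.35, "flower": 0.6},
            "DCL4b": {"root": 1.0, "stem": 1.5, "leaf": 2.0, "flower": 1.2},
        }
    )
    replicates: int = 3
    noise_sd: float = 0.1
    ref_cq: float = 18.0
    target_base_cq: float = 22.0


def make_cq_table(cfg: CqConfig):
    """Cq table implying the configured fold changes, plus the truth dict."""
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    rows = []
    for gene, folds in cfg.true_folds.items():
        if any(f <= 0 for f in folds.values()):
            raise ValueError("true folds must be positive")
        for sample in cfg.samples:
            for rep in range(1, cfg.replicates + 1):
                dcq = cfg.target_base_cq - cfg.ref_cq - np.log2(
                    folds[sample] / folds[cfg.calibrator]
                )
                rows.append(
                    {"sample": sample, "gene": gene, "replicate": rep,
                     "cq": cfg.ref_cq + dcq + rng.normal(0.0, cfg.noise_sd)}
                )
    for sample in cfg.samples:
        for rep in range(1, cfg.replicates + 1):
            rows.append(
                {"sample": sample, "gene": cfg.ref_gene, "replicate": rep,
                 "cq": cfg.ref_cq + rng.normal(0.0, cfg.noise_sd)}
            )
    return pd.DataFrame(rows), cfg.true_folds
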