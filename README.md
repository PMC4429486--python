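# dcltools

Analysis toolkit for plant **Dicer-like (DCL) gene families** and their
miRNA-mediated feedback regulation. It is written for molecular biologists
characterizing a DCL family in a species without a finished genome: given
cloned cDNAs, a genomic assembly, mature miRNA sequences and qPCR Cq
tables, it reproduces the standard desk analysis end to end —

- **miRNA target-site scoring**: construct the miRNA:mRNA duplex in a
  ~20-base window and compute the additive mismatch penalty score;
  scan whole transcripts for candidate sites.
- **miRNA precursor validation**: map a mature miRNA onto a genome
  (Hamming distance ≤ 2), fold the surrounding window into a stem-loop,
  and apply community annotation criteria (mature in one arm, well-paired
  mature:star duplex, bounded asymmetry); screen introns for embedded MIR
  hairpins.
- **Cross-species site conservation**: locate the orthologous site in each
  species, count substitutions (bulge nucleotide excluded), classify
  retained/lost, and map gain/loss events onto a species tree by Fitch
  parsimony.
- **Gene-family characterization**: longest ORF, deduced protein with
  molecular weight and theoretical pI, UTR partitioning, exon/intron
  structure by exact spliced alignment (GT-AG introns), GFF3 export.
- **Phylogeny**: protein distances (p or Poisson-corrected) with pairwise
  gap deletion, Saitou–Nei neighbor joining, bootstrap support.
- **Expression**: relative quantification by the comparative 2^−ΔΔCq
  method.
- **Synthetic data**: seeded generators for genomes with multi-exon genes,
  planted MIR hairpins and planted target sites of specified composition,
  with machine-readable ground truth — the test bed for everything above.

## The penalty score

A candidate target site is judged on the duplex between the mature miRNA
(positions numbered 1…n from its 5′ end) and the target window, read
antiparallel:

```
score = Σ_positions  w(pos) · cost(state)
cost:  mismatch = 1.0   G:U wobble = 0.5   bulged nucleotide = 1.0 (per nt)
w(pos) = 2.0 for miRNA positions 2–13 (the core), 1.0 elsewhere
```

A perfect duplex scores 0.0; established plant miRNA targets typically
score ≤ 3–4. The optimal duplex (allowing ≤ 2 bulged nucleotides in total)
is found by dynamic programming, with ties resolved toward fewer bulges
and bulges nearer the miRNA 3′ end. All constants live in
`PenaltyScheme` and every report echoes the scheme it used.

## Worked example

The canonical miR162 complementary site in *DCL1* transcripts is a
near-perfect duplex carrying one bulged target nucleotide outside the
core. The bundled synthetic panel (`dcltools.synthetic_panel`, a labelled
stand-in for the published ortholog set) reproduces the published decay
pattern of this site. Scoring the intact site and the four-substitution
variant:

```python
from dcltools.synthetic_panel import build_panel
from dcltools.duplex import align_duplex, count_substitutions

panel = build_panel()
for name in ("reference", "sm_like"):
    d = align_duplex(panel.mirna, panel.windows[name])
    print(f"--- {name} (score {d.score})")
    print(d.render(panel.mirna.seq, panel.windows[name].seq))
print("substitutions (bulge excluded):",
      count_substitutions(panel.windows["sm_like"], panel.windows["reference"],
                          exclude={panel.bulge_window_index}))
```

prints

```
--- reference (score 1.0)
5' GAAAGAGGGGTAGTAACTGAGC 3'  reference_DCL1_site
   ||||| ||||||||||||||||
3' CTTTC-CCCCATCATTGACTCG 5'  mir162_standin
--- sm_like (score 5.0)
5' GACCGAGCCGTAGTAACTGAGC 3'  sm_like_DCL1_site
   ||  | |  |||||||||||||
3' CTTTC-CCCCATCATTGACTCG 5'  mir162_standin
substitutions (bulge excluded): 4
```

The intact site costs 1.0 (the single non-core bulge, drawn as `-`);
four point substitutions outside the core raise the penalty to 5.0 — past
the 4.0 loss threshold, so the site is classified *lost*. The same
machinery run through `scan_targets`/`conservation` produces the
per-species TSV report with scores, substitution counts and
retained/lost status.

Command-line equivalents: `dcltools simulate`, `scan-targets`,
`score-duplex`, `locate-precursor`, `screen-introns`, `gene-structure`,
`conservation`, `nj-tree`, `ddcq`. Every run writes a `run_config.json`
snapshot into its output directory.

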