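# Methods

This note records the models, numerical choices and limitations behind
each stage of the toolkit, in the order the pipeline runs them.

## Duplex penalty scoring

Plant miRNA target recognition is evaluated on the duplex between the
mature miRNA and a target window of roughly one miRNA length, read
antiparallel, on the DNA alphabet (U→T on input; a G:U wobble is
G(miRNA):T(target) or T(miRNA):G(target)).

**Scheme.** Mismatch 1.0, G:U 0.5, 1.0 per bulged nucleotide; every
penalty doubled when its governing miRNA position lies in the core
(positions 2–13 from the miRNA 5′ end); at most 2 bulged nucleotides per
duplex. These are the common plant-target scoring conventions; all
constants are fields of `PenaltyScheme`, so a differently calibrated
scheme is a constructor call, not a code change. The governing position
for a bulged target nucleotide is the flanking miRNA position nearer the
5′ end; a bulged miRNA nucleotide governs itself.

**Windows.** `window_nt` (default 20) counts paired target nucleotides;
a physical window may carry up to `max_bulged_nt` extra bases, and a
miRNA longer than `window_nt` widens the cap to the miRNA length. This
resolves the ambiguity of whether a "20-base window" for a 21-nt miRNA
includes the bulged insertion: it does not.

**Optimal duplex.** A dynamic program over (miRNA prefix, reversed-window
prefix, bulges used) finds the minimum-penalty global alignment of the
two sequences with states pair/target-bulge/miRNA-bulge. Cell values are
(score, bulge count, tie key) tuples, so ties break first toward fewer
bulged nucleotides, then toward bulges nearer the miRNA 3′ end (the
canonical DCL1 site carries its bulge on the 3′ side). The aligner is
validated against exhaustive enumeration of all alignments for sequences
up to 22 nt.

**Scanning.** `scan_targets` runs one DP per window *end* (all window
lengths share a reversed prefix), merges overlapping candidate intervals
keeping the best score, filters by the cutoff (default 4.0), and sorts by
(score, position). The default cutoff plays the role that an expectation
threshold plays in web target-prediction servers; that substitution is
deliberate — no expectation model is implemented. Note the scanner's
contract is the best-scoring window at each locus: a heavily degraded
planted site can in principle be undercut by a truncated sub-window, which
is the scanner being right, not wrong.

## Hairpin folding and precursor annotation

**Folder.** Secondary structure comes from a weighted maximum-pairing
(Nussinov-style) dynamic program: Watson–Crick pairs weigh 2, G:U 1,
minimum loop 3 nt. Traceback is deterministic, preferring the outermost
compatible pair. The fill is O(n³) with a numba-jitted loop when numba is
importable and a diagonal-vectorized numpy fallback otherwise; both
produce identical tables. The folder is a pluggable backend (`backend=`
callable returning a pair table), so a thermodynamic folder can be
substituted without touching the criteria. Maximum-weight pairing is
deliberately chosen over free-energy minimization: it is dependency-free
and deterministic, and the downstream decision is a pass/fail screen, not
an energy estimate.

**Stem-loop extraction.** From the global pairing the folder reports the
single best stem-loop: nested pair chains are followed through
multiloops along the heaviest branch (small side-branches become
unpaired interruptions), and the chain with the most pairs wins, leftmost
on ties. Arms are the intervals spanned by the chain's 5′ and 3′ pair
partners.

**Criteria.** `PrecursorCriteria` operationalizes community MIR
annotation standards: (i) mature entirely within one arm; (ii) ≤ 4
unpaired mature nucleotides; (iii) mature/star length asymmetry ≤ 2 nt;
(iv) mature paired fraction ≥ 0.75; (v) the mature:star duplex must be a
near-contiguous helix — at most 2 distinct unpaired runs on *either*
strand of the duplex (the operational form of "no large internal loops or
bulges"); (vi) the stem must be precursor-scale, ≥ 25 pairs, so that the
duplex is embedded in a longer helix as in real pre-miRNAs. Criteria
(v)–(vi) compensate for the folder's known bias: maximum-pairing folding
gives random sequence large but ragged "stems" that thermodynamic folding
would reject. Every verdict records the numbers it compared and the
reasons for failure.

**Pipelines.** `locate_precursor` maps the mature sequence on both
strands (exhaustive Hamming scan, ≤ 2 mismatches), extracts ±150 nt
windows (precursors are typically 60–300 nt), folds and evaluates; only
passes are returned, so an absent miRNA yields an empty list.
`screen_introns` folds each intron (sliding 300-nt windows, 150-nt step,
for long introns) and slides a mature-length candidate span along each
arm; a pass in any window counts for the intron. An inverted repeat is
detected from either strand (the mature and its star both map), so a
planted locus typically reports on both strands; deduplication is by
locus interval.

## Spliced gene structure and protein descriptors

`infer_gene_structure` performs exact-match anchored spliced alignment:
exon seeds of ≥ 15 nt, maximal exact extension, introns ≥ 20 nt flanked
by GT…AG, depth-first search preferring the 5′-most splice donor. Exact
matching is appropriate because the input is the gene's own cloned cDNA;
a polymorphism-tolerant aligner is out of scope. The post-condition —
re-splicing the genomic by the returned exons reproduces the cDNA
byte-for-byte — is asserted in the function itself.

ORF finding scans the three forward frames (cloned cDNAs are
sense-strand; a `all_frames` flag adds the reverse strand), longest
ATG-to-stop wins, 5′-most on ties, and "no ORF" is an explicit `None`.
ORF length includes the stop codon, so protein length is len/3 − 1.
Molecular weight sums average residue masses plus one water (18.0153 Da);
pI solves the Henderson–Hasselbalch net charge (D, E, C, Y acidic; H, K,
R basic; both termini) for zero by bisection, with the EMBOSS pKa set as
the default and the table injectable — closed-source tools differ in
their pKa sets, which is why published pI values may deviate by ~0.1.

## Conservation and gain/loss

`extract_site` takes the best-scoring window with no cutoff, so an
ortholog's site is located even when heavily degraded. Cross-species
substitution counts are computed on miRNA-anchored coordinates: each
duplex maps miRNA position → facing target base, bulged target
nucleotides have no miRNA position and drop out automatically — the
"bulge excluded" convention. A raw count that also penalizes asymmetric
bulging is emitted alongside. Status is *retained* iff score ≤ the loss
threshold (default 4.0: plausible sites score ≤ 3–3.5, clearly lost
ones ≥ 5); the threshold is echoed in every report header.

Gain/loss mapping is unweighted Sankoff parsimony (exact on polytomies,
equivalent to Fitch on binary trees), validated against exhaustive
enumeration of internal labelings on trees ≤ 10 tips. Ambiguous nodes are
resolved preorder, preferring the parent's state; the root prefers
*present* on a tie. The event list (gain/loss per edge) and an annotated
newick are emitted.

## Phylogeny

Distances from a consumed protein alignment (alignment construction is
out of scope): pairwise deletion of gap columns, then p-distance or
Poisson correction −ln(1−p); the model is recorded in the output because
the choice is genuinely open — both are shipped, Poisson is the default.
Neighbor joining is the Saitou–Nei Q-criterion with lexicographic
tie-breaks; negative branch lengths are clamped to zero with the deficit
moved to the sibling edge; the final three lineages attach to a
trifurcating root for a stable unrooted newick. Bootstrap resamples
alignment columns with a seeded generator; support is the percentage of
replicates containing each original bipartition. NJ is validated to
exactly recover random additive matrices, and cross-checked against an
independent implementation's topology.

## Expression

2^−ΔΔCq with efficiency fixed at 2.0 (no efficiency correction): per
replicate ΔCq = Cq(target) − Cq(reference gene) within the same sample
and replicate; ΔΔCq subtracts the mean calibrator ΔCq; fold is the mean
of per-replicate 2^−ΔΔCq. The SD is taken over per-replicate folds
(matching error bars drawn on a linear fold axis); SD of ΔΔCq propagated
to the fold scale is available by flag. Folds are invariant to shifting
all Cq values of a sample, and the calibrator's fold is exactly 1 with a
single replicate.

## Synthetic data

The generators emulate the study conditions of a five-member DCL-like
family: 5 genes of 19–24 introns (exon counts 20–25), exons 80–300 nt,
GC 42%, intergenic gaps 0.3–1.2 kb, and a log-normal intron-length model
with two regimes — *compact* (median 100 nt) and *enlarged* (median
400 nt, σ = 0.6) to mimic intron-inflated families; no claim is made of
matching any real species' intron statistics, and there is no repeat/TE
model. Background sequence is i.i.d.; genes sit on the forward strand.
Planted MIR hairpins are 60-nt inverted repeats (loop 9 nt) with 2 point
imperfections placed opposite non-mature arm positions, so the mature is
fully paired; placements alternate intergenic/intronic.

Planted target sites start from the exact reverse complement and
introduce exactly the specified mismatches/wobbles/bulges, with three
construction rules that make the emitted truth exact: imperfections stay
≥ 3 nt from both duplex ends (so a scanning window cannot truncate a
planted penalty away for less than it costs), substituted bases are
chosen non-pairing against the facing base and both ±1 neighbours, and
the construction is verified against the aligner and the scanner —
positions are redrawn until the planted register is the true optimum over
the full window and every sub-window. Dense compositions that cannot be
realized this way raise rather than emit approximate truth. The
`synthetic_panel` module builds, with the same verified construction, a
stand-in ortholog panel whose substitution compositions reproduce the
published decay pattern of the canonical miR162:DCL1 site (intact site
1.0; one core substitution 3.0; two non-core 3.0; four non-core 5.0;
three core 7.0; four core 9.0; and a near-perfect miR397-style site at
3.5); its files and docstrings are labelled synthetic.

Protein families are star-phylogeny clades: a root sequence, clade
ancestors at 50% divergence, tips at 5% (defaults 5+4+4+4 tips,
300 columns, gap-free). Cq tables encode configured true folds with
Gaussian noise (default σ = 0.1 cycles, 3 technical replicates, flat
reference gene).

Because the generators are the test bed, passing tests demonstrate
correctness of the algorithms under these idealized conditions — exact
splice sites, noise-free cDNAs, i.i.d. background — not performance on
real genomes with repeats, paralogy, alternative splicing or sequencing
error.

## Problem sizes and determinism

Default verification scales: 200 duplex-vs-enumeration pairs (≤ 22 nt),
60 folds vs exhaustive pairing (≤ 14 nt), 50 random additive trees
(5–12 tips), 50 + 50 genomes for MIR recall/false passes, 200 planted
site specs, 100 Cq tables, 25 Fitch instances (≤ 10 tips), 200 bootstrap
replicates. Every stochastic step takes an explicit seed; identical seeds
give byte-identical outputs, including the CLI artifacts.

## Known limitations

- The Hamming mapper is a naive exhaustive scan — appropriate at
  desk scale, not for chromosome-scale genomes.
- Maximum-pairing folding has no thermodynamics; borderline hairpins
  (criteria (v)–(vi) above) are where it most disagrees with mfold-class
  folders.
- The spliced aligner tolerates no cDNA/genomic mismatches; truly
  polymorphic loci need pre-correction.
- No multiple-alignment construction, ML/Bayesian phylogenetics,
  expectation-model target prediction, or read-level small-RNA evidence.
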