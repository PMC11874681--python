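# Methods

This note documents the models, numerical choices and limitations behind
`opsinkit`, module by module, in the order the pipeline runs.

## Synthetic data (`synthio`)

The generator emulates a bulk retinal RNA-seq experiment over an opsin
repertoire. Its defaults are the study conditions the rest of the package
is tested under:

- **Reads**: paired-end 150 bp, insert uniform on [250, 300] bp,
  per-base substitution error 0.001 by default (no indels, no quality
  model — qualities are written as constant 'I' and never used).
- **Repertoire**: up to nine genes (rh1, sws1a/b, sws2b, rh2b, rh2a_1/2,
  lws_1/2) with coding lengths of 1.0–1.1 kb and four (sws1) or five
  exons at fixed fractional boundaries, matching typical vertebrate opsin
  gene structure. Paralog pairs (sws1, rh2a, lws) derive from a shared
  ancestor; all other genes are independent random CDSs, so cross-gene
  mapping ambiguity is negligible and the hard problem is confined to the
  paralog pairs, as in real data.
- **Paralog divergence**: `generate_paralog_pair` substitutes each copy
  independently at the stated per-site rate (start codon protected,
  stop-creating substitutions re-drawn among the remaining bases), then
  overwrites gene-conversion tracts with the donor copy. The default 1%
  per-copy rate yields ~2% pairwise divergence — roughly one diagnostic
  SNP every 50 bp, the regime where paired-end phasing is both necessary
  and sufficient.
- **Proportions**: target proportions are stated on the length-normalised
  scale used downstream, so source transcripts are drawn with weights
  `p_i × bp_i`; the realized length-normalised proportions then converge
  to the targets.
- **Synthetic SWS1 template**: the sws1 ancestor is a back-translated
  construct on the bovine-rhodopsin protein backbone (a synthetic stand-in,
  not a real SWS1 gene) so that tuning sites land at their canonical BRH
  coordinates; the α copy is set to A114/A118 and the β copy to S114/S118
  before conversion tracts are applied. Conversion tracts spanning codons
  114–118 therefore exchange the phenotypes between copies, reproducing
  the tuning-site swap that gene conversion causes in real paralogs.

**RNG protocol (v1), replayable.** One `numpy.random.default_rng(seed)`
generator per simulation; per pair, in order: source (one uniform draw
inverted against cumulative weights), insert length, fragment start
(uniform over all starts keeping the fragment on the transcript), then one
`random(read_len)` vector plus one base draw per error for mate 1 then
mate 2. Error vectors are drawn even at error rate 0 so the stream does not
depend on outcomes. Read names embed the truth (`pair<k>|src=<gene>`), so
no sidecar join is needed. The start is drawn *after* the insert length:
drawing it first would confine starts to `[0, L − insert_max]` and
structurally under-cover the transcript 3' end.

What the generator does **not** emulate: background (non-opsin)
transcriptome, rRNA, positional coverage bias, indel errors, quality decay,
strand-specific protocols. Tests passing on these libraries show the
arithmetic and the phasing logic are correct under the stated noise model;
they do not certify performance on degraded real libraries.

## Read mapping and phasing (`phasing`)

`map_reads` is a seed-and-extend mapper with the thresholds used for
paralog-resolution mapping of opsin transcriptomes: at most 2% mismatches
per read, gaps capped at 10% of the read and 12 bp per gap, 18 bp exact
seed words located through a 14-mer index, both strands, best hit per mate
per reference. Ungapped candidates are scored by direct array comparison;
candidates failing the ungapped threshold are re-evaluated gapped with
edlib (infix mode) and filtered by the same rules. A hand-written mapper is
used (rather than an external aligner) because the operation is defined by
these exact thresholds and must expose per-hit mismatch/gap counts to the
phasing step. On instances small enough to enumerate, the mapper agrees
with an exhaustive all-offset scorer (tested).

Diagnostic SNPs between two paralogs come from a global pairwise alignment
(Biopython `PairwiseAligner`; match 2, mismatch −1, gap open −5, extend −2):
one SNP per aligned column with differing non-gap bases. `phase_read_pairs`
collects the alleles each pair's two mates observe at every covered SNP:
all-A evidence → A, all-B → B, mixed → conflict, none → ambiguous. Linkage
is used only within a read pair; no cross-pair haplotype graph is built.
The conflict category has no counterpart in a by-eye workflow — it is the
automated equivalent of a read a curator would set aside.

`reconstruct_consensus` is a majority vote per scaffold position over the
assigned, ungapped reads. Exact ties emit IUPAC ambiguity codes rather than
an arbitrary base; zero-coverage positions emit N and are reported as
intervals with a warning. The consensus is invariant under read
duplication.

## Quantification (`quant`)

Counts are in mapped reads (mates). Each pair is assigned to the reference
where its mates align best (most mates mapped, then fewest
mismatches + gap bases). Pairs mapping to both members of a declared
paralog pair are routed through SNP phasing; conflicts are dropped, and
ambiguous pairs (covering no diagnostic SNP) are allocated fractionally in
proportion to each member's unambiguously assigned totals — discarding them
would bias low-divergence paralogs downward. An even 50/50 split is used in
the degenerate case of no unambiguous evidence at all.

Proportions follow the cone-class equations (see README): length-normalised
counts as percentages of the single-cone or double-cone class total, rod
against total opsin expression. Within-class percentages always sum to 100
(to 1e−9) and every proportion is invariant to uniform scaling of raw
counts. Stage summaries report mean ± sample (n−1) standard deviation to
one decimal — the conventional choice for n = 3 biological replicates —
with single-replicate groups reporting the mean alone; a gene missing from
a replicate is treated as 0 with a warning, while a gene absent from the
reference simply has no row, keeping "absent from genome" distinct from
"expressed below detection".

## Tuning classification (`tuning`)

Queries are globally aligned to bovine rhodopsin (BLOSUM62, gap open −11,
extend −1); each 1-based BRH position maps to the aligned query residue.
Alignments below a 15% identity floor are rejected as non-opsins, and query
lengths are bounded ([200, 500] by default) to catch frame errors early.
Classification is deliberately minimal: A114/A118 → "short" with a
representative λmax of 360 nm, S114/S118 → "long" with 370 nm, and any
other genotype is left unassigned with a warning — only the two tandem
genotypes carry an established spectral prediction, and the representative
values are the rounded midpoints of the published calibration ranges
(356–362 and 368–370 nm). No chromophore shift is modelled (A1 assumed).

## Conversion scanning (`convscan`)

An identity-based stand-in for likelihood recombination scanners, sized for
~1 kb alignments: windows of 90 columns every 15 columns; per window, each
query's identity to each clade consensus (leave-one-out for the query's own
clade; gap columns excluded from denominators); nearest clade by argmax.
Ties inherit the previous window's label — essential at ≤5% divergence
where many windows carry no informative site — and leading-edge ties with
no predecessor are treated as uninformative. Maximal runs of ≥ 2 windows
whose nearest clade differs from the query's expected clade become
conversion segments.

Window runs localize a breakpoint only to window resolution, and the true
breakpoint is in any case unidentifiable between the last informative site
supporting the expected clade and the first supporting the donor. Detected
boundaries are therefore refined to the midpoint of that informative-site
gap (the minimax choice); a boundary with no flanking expected-clade site
extends to the alignment edge, so a whole-sequence conversion yields a
single segment spanning the full alignment. Defaults (window 90, step 15,
min_run 2) resolve tracts ≥ ~120 bp while damping single-window noise.

`exon_signal` scores each exon as mean between-clade minus mean
within-clade p-distance (non-gap column pairs only) and ranks exons
descending — the quantity that justifies restricting paralog phylogenies to
the exons least homogenized by conversion.

## Reflectance (`reflectance`)

Calibration is `(sample − black) / (white − black) × 100` on a common
wavelength grid, with the division performed before scaling so the white
standard maps to exactly 100% and the black to exactly 0%; wavelengths
where white ≤ black are masked (NaN) with a warning and masks propagate
through replicate averaging. UV peaks are taken on a 5-point moving-average
smoothing (USB2000-class traces are noisy; edge windows shrink
symmetrically), within a 300–400 nm band by default, and accepted only if
the band maximum is a genuine local maximum of the smoothed curve — a
monotonic spectrum has no peak. Ties break to the lowest wavelength for
determinism. The synthetic-spectrum generator (Gaussian reflectance bump
plus white/black count levels with optional additive noise) exists because
no raw instrument traces ship with the package; only the calibration
arithmetic and peak logic are validated, not any instrument model.

## Pipeline (`pipeline`, `cli`)

A run is a plain-text YAML config with explicit seeds and exactly one of a
simulation block or real-input paths (FASTA references plus FASTQ
libraries). Child seeds derive deterministically from the top-level seed
via `numpy.random.SeedSequence`, all outputs carry a header naming the
package version and a SHA-256 config hash, and identical configs reproduce
byte-identical tables. UV-pattern presence enters only as a user-provided
annotation TSV joined against dual-sws1 expression flags — pattern scoring
is visual, not computational. Conversion scanning and exon ranking run in
simulation mode (where per-species sws1 alignments and clade labels are
known); real-input runs quantify and classify but skip the cross-species
scan, which needs a curated alignment.

## Problem sizes

Tests and the acceptance script run at desk scale by design: libraries of
2,000–50,000 read pairs (versus ~20 M fragments per library in a full
sequencing experiment), ten-seed recovery panels, and 20-replicate
conversion scans. At these depths every opsin present at ≥ 2% of its class
is detected and class proportions are recovered within ±2 percentage
points of truth; the statistical behaviour of the estimators, not raw
throughput, is what these sizes certify.

## Known limitations

- Phasing uses only within-pair linkage; haplotype blocks spanning regions
  with no read-pair bridge are reconstructed independently.
- The mapper is transcript-space and splice-unaware; it is not suitable
  for genome-space mapping.
- The conversion scanner assumes a gap-free or lightly gapped alignment of
  equal-length paralogs; heavily gapped alignments reduce its informative
  column count.
- Tuning predictions cover exactly two genotypes at two sites; other
  known SWS1 tuning sites are out of scope.
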