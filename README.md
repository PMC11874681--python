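# opsinkit

Paralog-aware quantification of visual-opsin gene expression from bulk
retinal RNA-seq, with SWS1 spectral-tuning classification, gene-conversion
segment detection, and reflectance-spectrum UV-peak extraction.

## The problem

Reef-fish retinas express a small family of opsin genes — the rod opsin
*rh1* and the cone opsins *sws1*, *sws2b*, *rh2b*, *rh2a* and *lws* — whose
relative expression sets the eye's spectral sensitivity and shifts across
development. Several damselfish lineages carry **duplicated UV opsins**
(*sws1α*/*sws1β*) that are only ~1–2% divergent at the nucleotide level.
Short-read assemblies routinely chimerize such paralogs, and naive read
counting cannot tell them apart, so both the reconstruction of each copy
and the quantification of its expression must work **SNP by SNP**: read
pairs are assigned to one paralog by the diagnostic alleles they carry,
with the paired-end insert extending each SNP's reach along the gene.
Recombination between the copies (gene conversion) further scrambles their
phylogenetic signal and can even exchange the spectral-tuning residues
between paralogs, which is why conversion tracts have to be located
explicitly.

`opsinkit` implements this whole desk-scale workflow as a tested Python
library with a synthetic-data generator in place of raw sequencing: opsin
repertoires with paralog pairs of controlled divergence and known
gene-conversion tracts, paired-end libraries (PE150, 250–300 bp inserts) at
known proportional expression, and fully replayable truth manifests.

## The core quantities

Mapped read counts $R_i$ are normalised by coding length $bp_i$ and
expressed as percentages of each **cone class** total (single cones express
*sws* genes; double cones express *rh2*/*lws* genes); the rod opsin is
expressed against total opsin expression:

$$R_{i,\mathrm{norm}} = \frac{R_i}{bp_i},\qquad
p_{i,SC} = \frac{R_{i,\mathrm{norm}}}{T_{SC}},\qquad
p_{i,DC} = \frac{R_{i,\mathrm{norm}}}{T_{DC}},\qquad
p_{rod} = \frac{R_{rh1,\mathrm{norm}}}{T_{\mathrm{opsins}}}$$

SWS1 copies are classified by the residues they carry at bovine-rhodopsin
(BRH) sites 114 and 118, which evolve in tandem: **A114/A118** marks the
shorter-wavelength UV phenotype (λmax ≈ 360 nm) and **S114/S118** the
longer-wavelength one (λmax ≈ 370 nm) — a ~10 nm shift. Gene-conversion
segments between paralog clades are detected from sliding-window
nearest-clade identity profiles with breakpoints refined to the informative
sites flanking each run, and reflectance traces are calibrated as
`100 × (sample − black) / (white − black)` before UV-band peak extraction.

## Worked example

Simulate a 20,000-pair retinal library at known proportions, map it, phase
the *sws1* paralogs, and quantify:

```python
from opsinkit import synthio, phasing, quant, tuning

records, _ = synthio.make_repertoire(seed=8, divergence=0.01)
props = {"sws1a": 0.12, "sws1b": 0.08, "rh2b": 0.30, "rh2a_1": 0.20, "rh1": 0.30}
r1, r2, truth = synthio.simulate_read_pairs(records, props, 20000, error_rate=0.001, seed=8)
reads = {n: (s1, s2) for (n, s1), (_, s2) in zip(r1, r2)}
hits = phasing.map_reads(reads, None, records)
counts, stats = quant.counts_from_alignments(
    hits, reads, records, [("sws1a", "sws1b"), ("rh2a_1", "rh2a_2"), ("lws_1", "lws_2")]
)
lengths = {r.gene_label: float(len(r)) for r in records}
print(quant.ExpressionTable.from_counts(counts, lengths).to_frame().to_string(index=False))
```

prints

```
  gene  cone_class   reads     bp  normalized  proportion_pct
 sws1a single_cone  4652.0 1044.0    4.455939       58.383534
 sws1b single_cone  3316.0 1044.0    3.176245       41.616466
 sws2b single_cone     0.0 1053.0    0.000000        0.000000
  rh2b double_cone 12010.0 1056.0   11.373106       59.514371
rh2a_1 double_cone  8170.0 1056.0    7.736742       40.485629
rh2a_2 double_cone     0.0 1056.0    0.000000        0.000000
 lws_1 double_cone     0.0 1092.0    0.000000        0.000000
 lws_2 double_cone     0.0 1092.0    0.000000        0.000000
   rh1         rod 11824.0 1065.0   11.102347       29.336846
```

The single-cone class splits 58.4% / 41.6% between the two UV paralogs
against a simulated truth of 60% / 40% (the deviation is sampling noise at
this depth), the double cones split 59.5% / 40.5% against 60% / 40%, and
rod opsin accounts for 29.3% of total opsin expression against a truth of
30%. Phasing statistics for the pair (`stats[("sws1a", "sws1b")]`) show
3,482 pairs assigned by diagnostic SNPs with 11 conflicts, and the tuning
classifier reports the two copies' phenotypes:

```python
by = {r.gene_label: r for r in records}
for lab in ("sws1a", "sws1b"):
    c = tuning.call_sws1(by[lab].cds, lab)
    print(lab, c.residue_114 + c.residue_118, c.phenotype, c.lambda_max_nm)
# sws1a AA short 360
# sws1b SS long 370
```

A command-line front end wraps the same machinery
(`opsinkit simulate | phase | quant | tune | convscan | reflect | run`);
`opsinkit run --config run.yaml` executes the full
simulate → map → phase → quantify → classify → scan pipeline and writes
per-individual expression tables, a stage summary, tuning calls, conversion
segments, exon ranks and a run manifest.

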