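"""Synthetic opsin repertoires and paired-end RNA-seq read simulation.

This module generates the inputs the rest of the pipeline consumes: labeled
opsin coding sequences (with exon intervals), paralog pairs of controlled
divergence with optional gene-conversion tracts, and paired-end short-read
libraries (150 bp mates, 250-300 bp inserts by default) at known proportional
expression. Every simulation is driven by a single seeded generator with a
fixed, documented draw order, so truth manifests are exactly replayable.

RNG protocol (version 1)
------------------------
``generate_paralog_pair``: one ``numpy.random.default_rng(seed)`` generator.
For copy A then copy B: draw ``rng.random(L)`` once; sites where the draw is
below ``divergence`` are mutated in ascending position order, each
consuming one ``rng.integers(3)`` to pick among the three alternative bases
(rotating forward if the pick would create an in-frame stop codon). The
start codon is protected: positions 0-2 are never mutated and consume no
``integers`` draw.

``simulate_read_pairs``: one ``numpy.random.default_rng(seed)`` generator.
For each pair ``k`` in order: (1) ``rng.random()`` inverted against the
cumulative source weights picks the source transcript; (2)
``rng.integers(insert_min, insert_max + 1)`` picks the insert length; (3)
``rng.integers(0, len - insert + 1)`` picks the fragment start (uniform over
all starts that keep the fragment on the transcript); (4) for
mate 1 then mate 2, ``rng.random(read_len)`` marks error positions (below
``error_rate``) and each error consumes one ``rng.integers(3)`` choosing among
the other three bases. The error draws happen even when ``error_rate`` is 0 so
the draw count is independent of the outcome.

Source weights are ``proportion * length`` (renormalised): proportions are
stated on the length-normalised scale used downstream, so the expected raw
read counts must be proportional to ``p_i * bp_i`` for the recovered
length-normalised proportions to match the targets.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "GENE_LABELS",
    "TranscriptRecord",
    "ConversionTract",
    "TruthManifest",
    "generate_paralog_pair",
    "simulate_read_pairs",
    "make_repertoire",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "write_manifest",
    "revcomp",
]

#: Opsin gene labels recognised throughout the package.
GENE_LABELS = (
    "rh1",
    "sws1a",
    "sws1b",
    "sws2b",
    "rh2b",
    "rh2a_1",
    "rh2a_2",
    "lws_1",
    "lws_2",
)

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_COMP = str.maketrans("ACGTNRYSWKMacgtn", "TGCANYRSWMKtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware for common codes)."""
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionTract:
    """A gene-conversion tract: ``[start, end)`` on the recipient CDS,
    overwritten by the ``donor`` paralog ('a' or 'b')."""

    start: int
    end: int
    donor: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid tract interval [{self.start}, {self.end})")
        if self.donor not in ("a", "b"):
            raise ValueError(f"tract donor must be 'a' or 'b', got {self.donor!r}")


@dataclass
class TranscriptRecord:
    """A labeled opsin coding sequence with exon intervals on the CDS.

    The CDS must start with ATG, be a positive multiple of 3 and contain no
    in-frame internal stop codon; exon intervals are disjoint, sorted and tile
    ``[0, len)``.
    """

    id: str
    species: str
    gene_label: str
    cds: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        n = len(self.cds)
        if n == 0 or n % 3 != 0:
            raise ValueError(f"{self.id}: CDS length {n} is not a positive multiple of 3")
        if not self.cds.startswith("ATG"):
            raise ValueError(f"{self.id}: CDS does not start with ATG")
        for i in range(3, n - 3, 3):
            if self.cds[i : i + 3] in _STOPS:
                raise ValueError(f"{self.id}: in-frame internal stop at {i}")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        prev = 0
        for s, e in self.exons:
            if s != prev or e <= s:
                raise ValueError(f"{self.id}: exon intervals must tile [0, {n})")
            prev = e
        if prev != n:
            raise ValueError(f"{self.id}: exons end at {prev}, expected {n}")

    def __len__(self) -> int:
        return len(self.cds)


@dataclass
class TruthManifest:
    """Ground truth for a simulated library.

    ``proportions`` are the target length-normalised expression fractions per
    transcript id (they sum to 1); ``realized_pairs`` counts the pairs actually
    drawn per transcript.
    """

    proportions: dict[str, float]
    n_pairs: int
    read_len: int
    insert_range: tuple[int, int]
    error_rate: float
    seed: int
    tracts: tuple[ConversionTract, ...] = ()
    realized_pairs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.fromiter(self.proportions.values(), dtype=float)
        if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be nonnegative and sum to 1")
        lo, hi = self.insert_range
        if lo < self.read_len:
            raise ValueError("insert minimum must be >= read length")
        if hi < lo:
            raise ValueError("insert range inverted")


# ---------------------------------------------------------------------------
# Sequence generation
# ---------------------------------------------------------------------------

_SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random CDS of ``n_codons`` codons: ATG followed by sense codons."""
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in idx)


def _creates_stop(seq: list[str], pos: int, base: str) -> bool:
    c0 = pos - pos % 3
    codon = "".join(seq[c0 : c0 + 3])
    codon = codon[: pos - c0] + base + codon[pos - c0 + 1 :]
    return codon in _STOPS


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution at probability ``rate``, never creating a stop.

    The start codon (positions 0-2) is protected and consumes no substitution
    draws.
    """
    chars = list(seq)
    u = rng.random(len(chars))
    for i in np.flatnonzero(u < rate):
        i = int(i)
        if i < 3:
            continue
        alts = [b for b in _BASES if b != chars[i]]
        k = int(rng.integers(3))
        for j in range(3):
            b = alts[(k + j) % 3]
            if not _creates_stop(chars, i, b):
                chars[i] = b
                break
    return "".join(chars)


def generate_paralog_pair(
    ancestor: str,
    divergence: float,
    tracts: Sequence[ConversionTract] = (),
    seed: int = 0,
) -> tuple[str, str, list[int]]:
    """Derive two paralogs from ``ancestor`` and apply gene-conversion tracts.

    Substitutions are placed independently in each copy at ``divergence`` per
    site (stop-codon-avoiding), so the expected pairwise divergence between
    the copies is a little under twice that rate. Each tract then overwrites the recipient's
    ``[start, end)`` with the donor copy's sequence. Returns
    ``(paralog_a, paralog_b, diagnostic_positions)`` where the diagnostic
    positions are the remaining mismatch positions.
    """
    if not (0 <= divergence < 0.2):
        raise ValueError(f"divergence {divergence} outside [0, 0.2)")
    L = len(ancestor)
    for t in tracts:
        if t.end > L:
            raise ValueError(f"tract [{t.start}, {t.end}) outside sequence of length {L}")
    rng = np.random.default_rng(seed)
    a = _mutate(ancestor, divergence, rng)
    b = _mutate(ancestor, divergence, rng)
    for t in tracts:
        if t.donor == "a":
            b = b[: t.start] + a[t.start : t.end] + b[t.end :]
        else:
            a = a[: t.start] + b[t.start : t.end] + a[t.end :]
    diag = [i for i in range(L) if a[i] != b[i]]
    return a, b, diag


# Exon boundary fractions (typical vertebrate opsin gene structure: five
# coding exons for most opsins, four for sws1).
_EXON_FRACTIONS = {
    4: (0.0, 0.30, 0.55, 0.80, 1.0),
    5: (0.0, 0.33, 0.52, 0.70, 0.85, 1.0),
}

_GENE_CODONS = {
    "rh1": 355,
    "sws1a": 348,  # BRH-backbone template length
    "sws1b": 348,
    "sws2b": 351,
    "rh2b": 352,
    "rh2a_1": 352,
    "rh2a_2": 352,
    "lws_1": 364,
    "lws_2": 364,
}

_PARALOG_ANCESTORS = {"sws1": ("sws1a", "sws1b"), "rh2a": ("rh2a_1", "rh2a_2"), "lws": ("lws_1", "lws_2")}

# Deterministic back-translation codons (one sense codon per amino acid).
_AA_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def backtranslate(protein: str) -> str:
    """Deterministic back-translation (one fixed sense codon per residue)."""
    return "".join(_AA_CODON[a] for a in protein)


def _sws1_ancestor_cds() -> str:
    """Synthetic SWS1 ancestor: a bovine-rhodopsin-backbone construct.

    The synthetic UV-opsin template reuses the rhodopsin numbering reference
    as a protein backbone so that tuning sites land at their canonical
    positions; residues 114 and 118 are set per paralog downstream.
    """
    from .tuning import BRH_REFERENCE

    return backtranslate(BRH_REFERENCE)


def _set_codon(cds: str, protein_pos_1based: int, codon: str) -> str:
    i = 3 * (protein_pos_1based - 1)
    return cds[:i] + codon + cds[i + 3 :]


def _exon_intervals(length: int, n_exons: int) -> tuple[tuple[int, int], ...]:
    fr = _EXON_FRACTIONS[n_exons]
    cuts = [round(f * length) for f in fr]
    cuts[0], cuts[-1] = 0, length
    return tuple((cuts[i], cuts[i + 1]) for i in range(n_exons))


def make_repertoire(
    seed: int,
    labels: Sequence[str] = GENE_LABELS,
    species: str = "synthetic",
    divergence: float = 0.01,
    tracts: Mapping[str, Sequence[ConversionTract]] | None = None,
) -> tuple[list[TranscriptRecord], dict[str, list[int]]]:
    """Build a synthetic opsin repertoire.

    Paralog pairs (sws1a/sws1b, rh2a_1/rh2a_2, lws_1/lws_2) are derived from a
    shared random ancestor at the stated pairwise ``divergence``; all other
    genes are independent random CDSs. ``tracts`` maps an ancestor key
    ('sws1', 'rh2a', 'lws') to conversion tracts applied within that pair.
    Returns the transcripts plus the diagnostic (mismatch) positions for each
    generated pair, keyed by ancestor name.
    """
    tracts = dict(tracts or {})
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    diagnostics: dict[str, list[int]] = {}
    wanted = set(labels)
    for anc, (la, lb) in _PARALOG_ANCESTORS.items():
        if not wanted & {la, lb}:
            continue
        if anc == "sws1":
            ancestor = _sws1_ancestor_cds()
        else:
            ancestor = _random_cds(_GENE_CODONS[la], rng)
        pair_seed = int(rng.integers(0, 2**31))
        a, b, _ = generate_paralog_pair(ancestor, divergence, seed=pair_seed)
        if anc == "sws1":
            # alpha copy: A114/A118 (shorter-wavelength); beta: S114/S118
            for pos in (114, 118):
                a = _set_codon(a, pos, _AA_CODON["A"])
                b = _set_codon(b, pos, _AA_CODON["S"])
        for t in tracts.get(anc, ()):
            if t.donor == "a":
                b = b[: t.start] + a[t.start : t.end] + b[t.end :]
            else:
                a = a[: t.start] + b[t.start : t.end] + a[t.end :]
        diagnostics[anc] = [i for i in range(len(a)) if a[i] != b[i]]
        seqs[la], seqs[lb] = a, b
    for lab in labels:
        if lab not in seqs:
            seqs[lab] = _random_cds(_GENE_CODONS[lab], rng)
    records = []
    for lab in labels:
        n_ex = 4 if lab.startswith("sws1") else 5
        cds = seqs[lab]
        records.append(
            TranscriptRecord(
                id=f"{species}_{lab}",
                species=species,
                gene_label=lab,
                cds=cds,
                exons=_exon_intervals(len(cds), n_ex),
            )
        )
    return records, diagnostics


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _apply_errors(read: list[str], error_rate: float, rng: np.random.Generator) -> None:
    u = rng.random(len(read))
    for i in np.flatnonzero(u < error_rate):
        i = int(i)
        alts = [b for b in _BASES if b != read[i]]
        read[i] = alts[int(rng.integers(3))]


def simulate_read_pairs(
    transcripts: Sequence[TranscriptRecord],
    proportions: Mapping[str, float],
    n_pairs: int,
    read_len: int = 150,
    insert_range: tuple[int, int] = (250, 300),
    error_rate: float = 0.0,
    seed: int = 0,
    out_r1: str | Path | None = None,
    out_r2: str | Path | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], TruthManifest]:
    """Simulate ``n_pairs`` paired-end reads at the target proportions.

    ``proportions`` maps gene labels to target length-normalised expression
    fractions (summing to 1). Mate 1 is the fragment 5' end on the transcript
    strand; mate 2 is the reverse complement of the fragment 3' end. Read
    names carry the truth as ``pair<k>|src=<gene_label>``. Records are
    returned as ``(name, sequence)`` lists and optionally written to FASTQ
    (constant quality 'I').
    """
    lut = {t.gene_label: t for t in transcripts}
    missing = set(proportions) - set(lut)
    if missing:
        raise ValueError(f"proportions name unknown transcripts: {sorted(missing)}")
    p = np.array([proportions[g] for g in proportions], dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be nonnegative and sum to 1")
    ins_lo, ins_hi = int(insert_range[0]), int(insert_range[1])
    if ins_lo < read_len:
        raise ValueError("insert minimum must be >= read length")
    genes = list(proportions)
    lengths = np.array([len(lut[g]) for g in genes], dtype=float)
    for g, L in zip(genes, lengths):
        if L < ins_hi:
            raise ValueError(f"transcript {g} shorter than insert max ({int(L)} < {ins_hi})")
    # weight by p_i * bp_i so length-normalised counts recover p_i
    w = p * lengths
    cw = np.cumsum(w / w.sum())

    rng = np.random.default_rng(seed)
    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    realized = {g: 0 for g in genes}
    for k in range(n_pairs):
        src = int(np.searchsorted(cw, rng.random(), side="right"))
        src = min(src, len(genes) - 1)
        gene = genes[src]
        realized[gene] += 1
        cds = lut[gene].cds
        insert = int(rng.integers(ins_lo, ins_hi + 1))
        start = int(rng.integers(0, len(cds) - insert + 1))
        frag = cds[start : start + insert]
        m1 = list(frag[:read_len])
        m2 = list(revcomp(frag[-read_len:]))
        _apply_errors(m1, error_rate, rng)
        _apply_errors(m2, error_rate, rng)
        name = f"pair{k}|src={gene}"
        r1.append((name, "".join(m1)))
        r2.append((name, "".join(m2)))

    manifest = TruthManifest(
        proportions=dict(proportions),
        n_pairs=n_pairs,
        read_len=read_len,
        insert_range=(ins_lo, ins_hi),
        error_rate=error_rate,
        seed=seed,
        realized_pairs=realized,
    )
    if out_r1 is not None:
        write_fastq(r1, out_r1)
    if out_r2 is not None:
        write_fastq(r2, out_r2)
    return r1, r2, manifest


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_fasta(records: Iterable[TranscriptRecord] | Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write sequences as FASTA wrapped at 80 columns."""
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, TranscriptRecord):
                name, seq = rec.id, rec.cds
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """4-line FASTQ, Phred+33, constant quality 'I' (qualities unused here)."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        return [(title.split()[0], seq.upper()) for title, seq, _ in FastqGeneralIterator(fh)]


def write_manifest(manifest: TruthManifest, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write per-transcript truth as TSV plus a JSON sidecar of parameters."""
    with open(tsv_path, "w") as fh:
        fh.write("gene\ttrue_proportion\trealized_pairs\n")
        for g, p in manifest.proportions.items():
            fh.write(f"{g}\t{p:.6g}\t{manifest.realized_pairs.get(g, 0)}\n")
    if json_path is not None:
        payload = {
            "n_pairs": manifest.n_pairs,
            "read_len": manifest.read_len,
            "insert_range": list(manifest.insert_range),
            "error_rate": manifest.error_rate,
            "seed": manifest.seed,
            "tracts": [vars(t) for t in manifest.tracts],
            "rng_protocol": 1,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)
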