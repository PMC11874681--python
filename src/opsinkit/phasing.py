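"""Read mapping, diagnostic-SNP calling, paired-end phasing and consensus.

Implements the paralog-untangling strategy used for opsin transcriptomes:
reads are mapped against the opsin coding regions under strict thresholds
(max 2% mismatches per read, max 10% gapped bases per read, max 12 bp per
gap, 18 bp seed words located through a 14-mer index), diagnostic SNPs
between two paralogs are called from a global pairwise alignment, and each
read pair is assigned to one paralog using the alleles its two mates observe
at those SNPs — the paired-end insert extends the reach of each SNP well
beyond a single read. A majority-rule consensus over the assigned reads then
reconstructs each paralog's full coding region.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import Align

from .synthio import TranscriptRecord, read_fastq, revcomp

__all__ = [
    "MapParams",
    "AlignmentHit",
    "DiagnosticSNP",
    "ConsensusResult",
    "map_reads",
    "call_diagnostic_snps",
    "phase_read_pairs",
    "reconstruct_consensus",
    "load_read_pairs",
    "write_hits_tsv",
    "write_partition_tsv",
]


@dataclass(frozen=True)
class MapParams:
    """Mapping thresholds: seed word 18, index word 14, <=2% mismatches per
    read, gaps capped at 10% of the read and 12 bp per gap."""

    word_length: int = 18
    index_word_length: int = 14
    max_mismatch_frac: float = 0.02
    max_gap_frac: float = 0.10
    max_gap_bp: int = 12


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    mate: int
    gene_label: str
    ref_start: int
    strand: str  # '+' or '-'
    mismatches: int
    gap_bases: int


@dataclass(frozen=True)
class DiagnosticSNP:
    """An alignment column where two paralogs carry different non-gap bases."""

    column: int
    allele_a: str
    allele_b: str
    pos_a: int
    pos_b: int


@dataclass
class ConsensusResult:
    sequence: str
    coverage: np.ndarray
    uncovered: list[tuple[int, int]]


# ---------------------------------------------------------------------------
# Read loading
# ---------------------------------------------------------------------------


def load_read_pairs(fastq_r1: str | Path, fastq_r2: str | Path) -> dict[str, tuple[str, str]]:
    """Load a FASTQ pair into ``{read_id: (mate1_seq, mate2_seq)}``.

    Raises if the two files disagree on read names (unpaired input).
    """
    r1 = read_fastq(fastq_r1)
    r2 = read_fastq(fastq_r2)
    if len(r1) != len(r2):
        raise ValueError(f"unpaired FASTQ: {len(r1)} vs {len(r2)} records")
    pairs: dict[str, tuple[str, str]] = {}
    for (n1, s1), (n2, s2) in zip(r1, r2):
        if n1 != n2:
            raise ValueError(f"unpaired FASTQ: read names {n1!r} != {n2!r}")
        pairs[n1] = (s1, s2)
    return pairs


def _as_read_dict(fastq_r1, fastq_r2) -> dict[str, tuple[str, str]]:
    if isinstance(fastq_r1, Mapping):
        return dict(fastq_r1)
    return load_read_pairs(fastq_r1, fastq_r2)


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------

_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i


def _seq_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class _RefIndex:
    """k-mer index over the forward strands of the references."""

    def __init__(self, references: Sequence[TranscriptRecord], k: int):
        if not references:
            raise ValueError("empty reference set")
        self.k = k
        self.seqs = {r.gene_label: r.cds for r in references}
        self.arrays = {r.gene_label: _seq_array(r.cds) for r in references}
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for label, seq in self.seqs.items():
            for pos in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[pos : pos + k], []).append((label, pos))


def _gapped_hit(q: str, ref: str, diag: int, params: MapParams) -> tuple[int, int, int] | None:
    """Gapped re-evaluation around a diagonal; returns (mm, gaps, ref_start)."""
    L = len(q)
    pad = params.max_gap_bp
    lo = max(0, diag - pad)
    hi = min(len(ref), diag + L + pad)
    res = edlib.align(q, ref[lo:hi], mode="HW", task="path")
    if res["editDistance"] < 0 or res["cigar"] is None:
        return None
    mm = gaps = 0
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "X":
            mm += n
        elif ch in "ID":
            if n > params.max_gap_bp:
                return None
            gaps += n
    if mm > int(params.max_mismatch_frac * L):
        return None
    if gaps > min(params.max_gap_bp, int(params.max_gap_frac * L)):
        return None
    return mm, gaps, lo + res["locations"][0][0]


def _read_hits(
    read: str, mate: int, read_id: str, index: _RefIndex, params: MapParams
) -> list[AlignmentHit]:
    """Best hit per reference for one mate, over both strands."""
    best: dict[str, AlignmentHit] = {}
    k = index.k
    w = params.word_length
    for strand, q in (("+", read), ("-", revcomp(read))):
        L = len(q)
        if L < k:
            continue
        qarr = _seq_array(q)
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        cands: set[tuple[str, int]] = set()
        for off in offsets:
            for label, pos in index.kmers.get(q[off : off + k], ()):
                diag = pos - off
                if w <= L:
                    # require an exact seed word of the full word length
                    eo = min(off, L - w)
                    ref = index.arrays[label]
                    if eo + diag < 0 or eo + diag + w > len(ref):
                        continue
                    if not np.array_equal(ref[eo + diag : eo + diag + w], qarr[eo : eo + w]):
                        continue
                cands.add((label, diag))
        max_mm = int(params.max_mismatch_frac * L)
        for label, diag in cands:
            ref = index.arrays[label]
            hit = None
            if 0 <= diag and diag + L <= len(ref):
                mm = int(np.count_nonzero(ref[diag : diag + L] != qarr))
                if mm <= max_mm:
                    hit = AlignmentHit(read_id, mate, label, diag, strand, mm, 0)
            if hit is None:
                g = _gapped_hit(q, index.seqs[label], diag, params)
                if g is not None:
                    mm, gaps, start = g
                    hit = AlignmentHit(read_id, mate, label, start, strand, mm, gaps)
            if hit is None:
                continue
            prev = best.get(label)
            if (
                prev is None
                or (hit.mismatches + hit.gap_bases, hit.ref_start)
                < (prev.mismatches + prev.gap_bases, prev.ref_start)
            ):
                best[label] = hit
    return list(best.values())


def map_reads(
    fastq_r1,
    fastq_r2,
    references: Sequence[TranscriptRecord],
    params: MapParams | None = None,
) -> list[AlignmentHit]:
    """Map a paired library against opsin references, both strands.

    ``fastq_r1``/``fastq_r2`` may be file paths or a single pre-loaded dict
    ``{read_id: (mate1, mate2)}`` passed as the first argument. Hits violating
    the mismatch/gap thresholds are discarded; the best hit per mate per
    reference is retained.
    """
    params = params or MapParams()
    reads = _as_read_dict(fastq_r1, fastq_r2)
    index = _RefIndex(references, params.index_word_length)
    hits: list[AlignmentHit] = []
    for read_id, (s1, s2) in reads.items():
        hits.extend(_read_hits(s1, 1, read_id, index, params))
        hits.extend(_read_hits(s2, 2, read_id, index, params))
    return hits


# ---------------------------------------------------------------------------
# Diagnostic SNPs
# ---------------------------------------------------------------------------


def _pairwise_indices(a: str, b: str) -> np.ndarray:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner.align(a, b)[0].indices


def call_diagnostic_snps(paralog_a: str, paralog_b: str) -> list[DiagnosticSNP]:
    """Diagnostic SNPs between two paralogs from a global pairwise alignment.

    One SNP per aligned column with differing non-gap bases, ordered by
    column; gap columns are excluded by definition.
    """
    if not paralog_a or not paralog_b:
        raise ValueError("cannot call SNPs against an empty sequence")
    idx = _pairwise_indices(paralog_a, paralog_b)
    snps: list[DiagnosticSNP] = []
    for col in range(idx.shape[1]):
        ia, ib = int(idx[0, col]), int(idx[1, col])
        if ia < 0 or ib < 0:
            continue
        ba, bb = paralog_a[ia], paralog_b[ib]
        if ba != bb:
            snps.append(DiagnosticSNP(col, ba, bb, ia, ib))
    return snps


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------


def _observed_base(hit: AlignmentHit, seq: str, pos: int) -> str | None:
    """Base of the aligned read at reference position ``pos`` (ungapped hits)."""
    if hit.gap_bases:
        return None
    oriented = seq if hit.strand == "+" else revcomp(seq)
    off = pos - hit.ref_start
    if 0 <= off < len(oriented):
        return oriented[off]
    return None


def phase_read_pairs(
    hits: Iterable[AlignmentHit],
    reads: Mapping[str, tuple[str, str]],
    snps: Sequence[DiagnosticSNP],
    label_a: str,
    label_b: str,
) -> dict[str, str]:
    """Assign each mapped pair to paralog A or B via its diagnostic alleles.

    For every SNP covered by either mate the observed base is compared with
    the two alleles; all-A evidence -> 'A', all-B -> 'B', mixed -> 'conflict',
    none covered -> 'ambiguous'. Returns ``{pair_id: assignment}`` with every
    mapped pair appearing exactly once.
    """
    by_pair: dict[str, dict[tuple[int, str], AlignmentHit]] = {}
    for h in hits:
        if h.gene_label not in (label_a, label_b):
            continue
        slot = by_pair.setdefault(h.read_id, {})
        key = (h.mate, h.gene_label)
        prev = slot.get(key)
        if prev is None or h.mismatches + h.gap_bases < prev.mismatches + prev.gap_bases:
            slot[key] = h
    partition: dict[str, str] = {}
    for pair_id, slot in by_pair.items():
        seqs = reads.get(pair_id)
        if seqs is None:
            raise KeyError(f"read pair {pair_id!r} missing from reads")
        votes: set[str] = set()
        for snp in snps:
            for mate in (1, 2):
                seq = seqs[mate - 1]
                base = None
                h = slot.get((mate, label_a))
                if h is not None:
                    base = _observed_base(h, seq, snp.pos_a)
                if base is None:
                    h = slot.get((mate, label_b))
                    if h is not None:
                        base = _observed_base(h, seq, snp.pos_b)
                if base == snp.allele_a:
                    votes.add("A")
                elif base == snp.allele_b:
                    votes.add("B")
        if not votes:
            partition[pair_id] = "ambiguous"
        elif votes == {"A"}:
            partition[pair_id] = "A"
        elif votes == {"B"}:
            partition[pair_id] = "B"
        else:
            partition[pair_id] = "conflict"
    return partition


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

_IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}


def reconstruct_consensus(
    partition: Mapping[str, str],
    hits: Iterable[AlignmentHit],
    reads: Mapping[str, tuple[str, str]],
    scaffold: TranscriptRecord,
    target: str = "A",
) -> ConsensusResult:
    """Majority-rule consensus over the reads phased to ``target``.

    Ties emit IUPAC ambiguity codes; zero-coverage positions emit N and are
    reported (and warned about) as intervals. Output length equals the
    scaffold length.
    """
    wanted = {pid for pid, a in partition.items() if a == target}
    if not wanted:
        raise ValueError(f"no read pairs assigned to {target!r}")
    L = len(scaffold.cds)
    counts = np.zeros((L, 4), dtype=np.int64)
    best: dict[tuple[str, int], AlignmentHit] = {}
    for h in hits:
        if h.gene_label != scaffold.gene_label or h.read_id not in wanted or h.gap_bases:
            continue
        key = (h.read_id, h.mate)
        prev = best.get(key)
        if prev is None or h.mismatches < prev.mismatches:
            best[key] = h
    for (pid, mate), h in best.items():
        seq = reads[pid][mate - 1]
        oriented = seq if h.strand == "+" else revcomp(seq)
        arr = _ENC[_seq_array(oriented)]
        valid = _seq_array(oriented) != ord("N")
        s = h.ref_start
        e = min(L, s + len(oriented))
        span = np.arange(s, e)
        np.add.at(counts, (span[valid[: e - s]], arr[: e - s][valid[: e - s]]), 1)
    total = counts.sum(axis=1)
    out = []
    for i in range(L):
        if total[i] == 0:
            out.append("N")
            continue
        mx = counts[i].max()
        tied = frozenset("ACGT"[j] for j in range(4) if counts[i, j] == mx)
        out.append(_IUPAC[tied])
    uncovered: list[tuple[int, int]] = []
    i = 0
    while i < L:
        if total[i] == 0:
            j = i
            while j < L and total[j] == 0:
                j += 1
            uncovered.append((i, j))
            i = j
        else:
            i += 1
    if uncovered:
        warnings.warn(f"zero coverage over intervals {uncovered} in {scaffold.gene_label} consensus")
    return ConsensusResult("".join(out), total, uncovered)


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_hits_tsv(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Minimal SAM-like TSV: read, mate, ref, pos, strand, NM."""
    with open(path, "w") as fh:
        fh.write("read\tmate\tref\tpos\tstrand\tNM\tgap_bases\n")
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.mate}\t{h.gene_label}\t{h.ref_start}\t{h.strand}\t{h.mismatches}\t{h.gap_bases}\n"
            )


def write_partition_tsv(partition: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pair\tassignment\n")
        for pid, a in partition.items():
            fh.write(f"{pid}\t{a}\n")
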