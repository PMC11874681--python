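"""Mapper thresholds, SNP calling, paired-end phasing and consensus."""

import warnings

import numpy as np
import pytest

from opsinkit import phasing, synthio
from opsinkit.phasing import (
    AlignmentHit,
    MapParams,
    call_diagnostic_snps,
    map_reads,
    phase_read_pairs,
    reconstruct_consensus,
)
from opsinkit.synthio import TranscriptRecord, revcomp


def _refs(repertoire):
    records, _ = repertoire
    return records


def _mutate_at(seq, positions):
    chars = list(seq)
    for p in positions:
        chars[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[p]]
    return "".join(chars)


def _brute_force_hits(read, refs, params=MapParams()):
    """Exhaustive all-offset ungapped scorer (independent mapping oracle)."""
    out = []
    for ref in refs:
        L = len(read)
        max_mm = int(params.max_mismatch_frac * L)
        for strand, q in (("+", read), ("-", revcomp(read))):
            best = None
            for s in range(len(ref.cds) - L + 1):
                mm = sum(a != b for a, b in zip(ref.cds[s : s + L], q))
                if mm <= max_mm and (best is None or mm < best[0]):
                    best = (mm, s, strand)
            if best:
                out.append((ref.gene_label, best[2], best[1], best[0]))
    return out


class TestMapReads:
    def test_exact_substring_maps_at_offset(self, repertoire):
        refs = _refs(repertoire)
        read = refs[0].cds[100:250]
        reads = {"p0": (read, revcomp(read))}
        hits = [h for h in map_reads(reads, None, refs) if h.gene_label == refs[0].gene_label]
        m1 = next(h for h in hits if h.mate == 1)
        assert (m1.ref_start, m1.strand, m1.mismatches, m1.gap_bases) == (100, "+", 0, 0)

    def test_mismatches_beyond_two_percent_discarded(self, repertoire):
        refs = _refs(repertoire)
        ref = refs[0]
        clean = ref.cds[200:350]
        over = _mutate_at(clean, [10, 50, 90, 130])  # 4 > floor(0.02 * 150) = 3
        under = _mutate_at(clean, [10, 50, 90])
        hits_over = [h for h in map_reads({"p": (over, over)}, None, [ref]) if h.mate == 1]
        hits_under = [h for h in map_reads({"p": (under, under)}, None, [ref]) if h.mate == 1]
        assert hits_over == []
        assert hits_under and hits_under[0].mismatches == 3

    def test_reverse_complement_read_hits_minus_strand(self, repertoire):
        refs = _refs(repertoire)
        ref = refs[2]
        read = revcomp(ref.cds[300:450])
        hits = [h for h in map_reads({"p": (read, read)}, None, [ref]) if h.mate == 1]
        assert hits[0].strand == "-"
        assert hits[0].ref_start == 300

    def test_agrees_with_exhaustive_offset_scanner(self, repertoire, rng):
        """Seed-and-extend must match a brute-force all-offset oracle."""
        refs = _refs(repertoire)[:3]
        for trial in range(20):
            ref = refs[int(rng.integers(len(refs)))]
            s = int(rng.integers(0, len(ref.cds) - 150))
            read = ref.cds[s : s + 150]
            n_mm = int(rng.integers(0, 3))
            read = _mutate_at(read, list(rng.choice(150, size=n_mm, replace=False)))
            if rng.random() < 0.5:
                read = revcomp(read)
            got = {
                (h.gene_label, h.strand, h.ref_start, h.mismatches)
                for h in map_reads({"p": (read, read)}, None, refs)
                if h.mate == 1 and h.gap_bases == 0
            }
            assert got == set(_brute_force_hits(read, refs))

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            map_reads({"p": ("ACGT" * 40, "ACGT" * 40)}, None, [])

    def test_unpaired_fastq_rejected(self, tmp_path):
        synthio.write_fastq([("a", "ACGT" * 40)], tmp_path / "r1.fq")
        synthio.write_fastq([("b", "ACGT" * 40)], tmp_path / "r2.fq")
        with pytest.raises(ValueError, match="unpaired"):
            phasing.load_read_pairs(tmp_path / "r1.fq", tmp_path / "r2.fq")


class TestDiagnosticSnps:
    def test_identical_sequences_yield_no_snps(self):
        seq = synthio._random_cds(200, np.random.default_rng(0))
        assert call_diagnostic_snps(seq, seq) == []

    def test_two_point_differences_called_exactly(self):
        a = synthio._random_cds(250, np.random.default_rng(1))
        b = _mutate_at(a, [10, 500])
        snps = call_diagnostic_snps(a, b)
        assert [(s.pos_a, s.pos_b) for s in snps] == [(10, 10), (500, 500)]
        assert all(s.allele_a != s.allele_b for s in snps)

    def test_gap_columns_excluded(self):
        a = synthio._random_cds(250, np.random.default_rng(2))
        b = a[:300] + a[303:]  # 3-nt deletion introduces gap columns
        snps = call_diagnostic_snps(a, b)
        assert all(s.allele_a != "-" and s.allele_b != "-" for s in snps)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            call_diagnostic_snps("", "ACGT")


class TestPhaseReadPairs:
    @pytest.fixture()
    def pair_setup(self):
        a = synthio._random_cds(300, np.random.default_rng(3))
        b = _mutate_at(a, [100, 600])
        ra = TranscriptRecord("a", "sp", "sws1a", a, ((0, len(a)),))
        rb = TranscriptRecord("b", "sp", "sws1b", b, ((0, len(b)),))
        snps = call_diagnostic_snps(a, b)
        return ra, rb, snps

    def test_single_snp_evidence_assigns_pair(self, pair_setup):
        ra, rb, snps = pair_setup
        read = ra.cds[50:200]  # covers SNP at 100 with allele A
        reads = {"p": (read, revcomp(ra.cds[150:300]))}
        hits = phasing.map_reads(reads, None, [ra, rb])
        part = phase_read_pairs(hits, reads, snps, "sws1a", "sws1b")
        assert part["p"] == "A"

    def test_discordant_mates_flagged_conflict(self, pair_setup):
        ra, rb, snps = pair_setup
        # mate 1 shows allele A at SNP 100; mate 2 shows allele B at SNP 600
        reads = {"p": (ra.cds[50:200], revcomp(rb.cds[550:700]))}
        hits = phasing.map_reads(reads, None, [ra, rb])
        part = phase_read_pairs(hits, reads, snps, "sws1a", "sws1b")
        assert part["p"] == "conflict"

    def test_pair_covering_no_snp_is_ambiguous(self, pair_setup):
        ra, rb, snps = pair_setup
        reads = {"p": (ra.cds[200:350], revcomp(ra.cds[300:450]))}
        hits = phasing.map_reads(reads, None, [ra, rb])
        part = phase_read_pairs(hits, reads, snps, "sws1a", "sws1b")
        assert part["p"] == "ambiguous"

    def test_error_free_library_phases_to_truth(self, repertoire):
        records, _ = repertoire
        pair = [r for r in records if r.gene_label in ("sws1a", "sws1b")]
        props = {"sws1a": 0.6, "sws1b": 0.4}
        r1, r2, _ = synthio.simulate_read_pairs(records, props, 1500, error_rate=0.0, seed=9)
        reads = {n: (s1, s2) for (n, s1), (_, s2) in zip(r1, r2)}
        hits = phasing.map_reads(reads, None, pair)
        snps = call_diagnostic_snps(pair[0].cds, pair[1].cds)
        part = phase_read_pairs(hits, reads, snps, "sws1a", "sws1b")
        assert set(part) == set(reads)
        for pid, call in part.items():
            truth = pid.split("src=")[1]
            if call == "A":
                assert truth == "sws1a"
            elif call == "B":
                assert truth == "sws1b"
            else:
                assert call == "ambiguous"  # error-free reads cannot conflict


class TestConsensus:
    def _phased_library(self, repertoire, n_pairs=1500):
        records, _ = repertoire
        pair = [r for r in records if r.gene_label in ("sws1a", "sws1b")]
        r1, r2, _ = synthio.simulate_read_pairs(
            records, {"sws1a": 0.5, "sws1b": 0.5}, n_pairs, error_rate=0.0, seed=13
        )
        reads = {n: (s1, s2) for (n, s1), (_, s2) in zip(r1, r2)}
        hits = phasing.map_reads(reads, None, pair)
        snps = call_diagnostic_snps(pair[0].cds, pair[1].cds)
        part = phase_read_pairs(hits, reads, snps, "sws1a", "sws1b")
        return pair, reads, hits, part

    def test_error_free_tiled_coverage_recovers_true_paralog(self, repertoire):
        """Full tiled coverage reconstructs the paralog base-for-base."""
        records, _ = repertoire
        pair = [r for r in records if r.gene_label in ("sws1a", "sws1b")]
        a = pair[0].cds
        reads = {}
        for i, s in enumerate(list(range(0, len(a) - 150, 25)) + [len(a) - 150]):
            reads[f"t{i}"] = (a[s : s + 150], synthio.revcomp(a[s : s + 150]))
        hits = phasing.map_reads(reads, None, pair)
        snps = call_diagnostic_snps(pair[0].cds, pair[1].cds)
        part = phase_read_pairs(hits, reads, snps, "sws1a", "sws1b")
        res = reconstruct_consensus(part, hits, reads, pair[0], target="A")
        assert res.sequence == a
        assert res.uncovered == []

    def test_error_free_library_consensus_matches_truth_where_covered(self, repertoire):
        pair, reads, hits, part = self._phased_library(repertoire)
        res = reconstruct_consensus(part, hits, reads, pair[0], target="A")
        truth = pair[0].cds
        covered = [i for i in range(len(truth)) if res.coverage[i] > 0]
        assert len(covered) > 0.98 * len(truth)
        assert all(res.sequence[i] == truth[i] for i in covered)

    def test_consensus_idempotent_under_read_duplication(self, repertoire):
        pair, reads, hits, part = self._phased_library(repertoire, 600)
        res1 = reconstruct_consensus(part, hits, reads, pair[0], target="A")
        dup_reads = dict(reads) | {f"{k}~dup": v for k, v in reads.items()}
        dup_hits = list(hits) + [
            phasing.AlignmentHit(f"{h.read_id}~dup", h.mate, h.gene_label, h.ref_start, h.strand, h.mismatches, h.gap_bases)
            for h in hits
        ]
        dup_part = dict(part) | {f"{k}~dup": v for k, v in part.items()}
        res2 = reconstruct_consensus(dup_part, dup_hits, dup_reads, pair[0], target="A")
        assert res2.sequence == res1.sequence

    def test_uncovered_interval_emits_n_and_warning(self):
        ref = TranscriptRecord("r", "sp", "rh1", synthio._random_cds(200, np.random.default_rng(4)), ((0, 600),))
        read = ref.cds[:150]
        reads = {"p": (read, read)}
        hits = [AlignmentHit("p", 1, "rh1", 0, "+", 0, 0)]
        with pytest.warns(UserWarning, match="zero coverage"):
            res = reconstruct_consensus({"p": "A"}, hits, reads, ref, target="A")
        assert res.sequence[:150] == ref.cds[:150]
        assert set(res.sequence[150:]) == {"N"}
        assert res.uncovered == [(150, 600)]

    def test_even_tie_emits_iupac_code(self):
        ref = TranscriptRecord("r", "sp", "rh1", "ATG" + "A" * 147, ((0, 150),))
        r_a = "ATG" + "A" * 147
        r_g = "ATG" + "G" + "A" * 146  # disagrees at position 3: A vs G
        reads = {"p1": (r_a, r_a), "p2": (r_g, r_g)}
        hits = [AlignmentHit("p1", 1, "rh1", 0, "+", 0, 0), AlignmentHit("p2", 1, "rh1", 0, "+", 1, 0)]
        res = reconstruct_consensus({"p1": "A", "p2": "A"}, hits, reads, ref, target="A")
        assert res.sequence[3] == "R"  # A/G ambiguity

    def test_no_assigned_reads_rejected(self):
        ref = TranscriptRecord("r", "sp", "rh1", "ATG" + "A" * 147, ((0, 150),))
        with pytest.raises(ValueError):
            reconstruct_consensus({"p": "B"}, [], {}, ref, target="A")
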