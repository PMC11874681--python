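"""Proportional-expression arithmetic, invariants and count assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opsinkit import phasing, quant, synthio
from opsinkit.quant import (
    ExpressionTable,
    classify_gene,
    cone_proportions,
    counts_from_alignments,
    normalize_counts,
    rod_proportion,
    stage_summary,
)


class TestClassifyGene:
    @pytest.mark.parametrize(
        "gene,cls",
        [
            ("sws1a", quant.SINGLE_CONE),
            ("sws1b", quant.SINGLE_CONE),
            ("sws2b", quant.SINGLE_CONE),
            ("rh2b", quant.DOUBLE_CONE),
            ("rh2a_1", quant.DOUBLE_CONE),
            ("lws_1", quant.DOUBLE_CONE),
            ("rh1", quant.ROD),
        ],
    )
    def test_cone_class_assignment(self, gene, cls):
        assert classify_gene(gene) == cls

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            classify_gene("cyp27c1")


class TestNormalizeCounts:
    def test_ratio_identity_and_zero(self):
        out = normalize_counts({"rh1": 1065, "sws1a": 0}, {"rh1": 1065, "sws1a": 1000})
        assert out == {"rh1": 1.0, "sws1a": 0.0}

    def test_hand_arithmetic(self):
        out = normalize_counts({"a": 300, "b": 100}, {"a": 1500, "b": 1000})
        assert out == {"a": 0.2, "b": 0.1}

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts({"a": 1}, {})


class TestConeProportions:
    def test_single_cone_split(self):
        out = cone_proportions({"sws1a": 3.0, "sws2b": 1.0})
        assert out == {"sws1a": 75.0, "sws2b": 25.0}

    def test_single_member_class_is_100(self):
        assert cone_proportions({"sws1a": 0.42})["sws1a"] == 100.0

    @pytest.mark.parametrize("u", [0.1, 1.0, 37.5])
    def test_scale_invariance(self, u):
        out = cone_proportions({"rh2b": 0.678 * u, "rh2a_1": 0.322 * u})
        assert out["rh2b"] == pytest.approx(67.8)
        assert out["rh2a_1"] == pytest.approx(32.2)

    def test_zero_class_total_rejected(self):
        with pytest.raises(ValueError):
            cone_proportions({"sws1a": 0.0, "rh2b": 1.0})

    def test_rod_excluded_from_cone_totals(self):
        out = cone_proportions({"sws1a": 1.0, "rh1": 99.0})
        assert out == {"sws1a": 100.0}


class TestRodProportion:
    @pytest.mark.parametrize(
        "rod,cones,expected", [(1.0, 1.0, 50.0), (0.0, 1.0, 0.0), (3.0, 1.0, 75.0)]
    )
    def test_rod_fraction_of_total(self, rod, cones, expected):
        norm = {"rh1": rod, "rh2b": cones}
        assert rod_proportion(norm) == pytest.approx(expected)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            rod_proportion({"rh1": 0.0, "rh2b": 0.0})


class TestEquationInvariants:
    @settings(derandomize=True, max_examples=50)
    @given(
        counts=st.lists(st.integers(1, 10**6), min_size=5, max_size=5),
        scale=st.floats(0.01, 1000.0),
    )
    def test_proportions_invariant_to_uniform_count_scaling(self, counts, scale):
        genes = ["sws1a", "sws1b", "rh2b", "lws_1", "rh1"]
        lengths = {g: 900.0 + 50 * i for i, g in enumerate(genes)}
        raw = dict(zip(genes, map(float, counts)))
        scaled = {g: c * scale for g, c in raw.items()}
        t1 = ExpressionTable.from_counts(raw, lengths)
        t2 = ExpressionTable.from_counts(scaled, lengths)
        for g in genes[:-1]:
            assert t2.proportions[g] == pytest.approx(t1.proportions[g], rel=1e-9)
        assert t2.p_rod == pytest.approx(t1.p_rod, rel=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(counts=st.lists(st.integers(0, 10**6), min_size=5, max_size=5))
    def test_class_proportions_sum_to_100(self, counts):
        genes = ["sws1a", "sws1b", "rh2b", "lws_1", "rh1"]
        raw = dict(zip(genes, map(float, counts)))
        lengths = {g: 1000.0 for g in genes}
        norm = normalize_counts(raw, lengths)
        sc = [g for g in genes[:2] if True]
        if sum(norm[g] for g in sc) > 0 and norm["rh2b"] + norm["lws_1"] > 0:
            props = cone_proportions(norm)
            assert sum(props[g] for g in ("sws1a", "sws1b")) == pytest.approx(100.0, abs=1e-9)
            assert sum(props[g] for g in ("rh2b", "lws_1")) == pytest.approx(100.0, abs=1e-9)
        if sum(norm.values()) > 0:
            assert 0.0 <= rod_proportion(norm) <= 100.0


class TestStageSummary:
    def _table(self, sc_split, species="sp", stage="adult"):
        counts = {"sws1a": sc_split, "sws1b": 100 - sc_split, "rh2b": 50, "rh1": 50}
        lengths = {g: 1000.0 for g in counts}
        return ExpressionTable.from_counts(counts, lengths, species=species, stage=stage)

    def test_identical_replicates_have_zero_sd(self):
        df = stage_summary([self._table(40), self._table(40), self._table(40)])
        row = df[df.gene == "sws1a"].iloc[0]
        assert row["sd"] == 0.0
        assert row["formatted"] == "40.0 ± 0.0"

    def test_two_replicate_sample_sd(self):
        df = stage_summary([self._table(40), self._table(60)])
        row = df[df.gene == "sws1a"].iloc[0]
        assert row["mean"] == pytest.approx(50.0)
        assert row["sd"] == pytest.approx(math.sqrt(200.0))  # sample sd of {40, 60}
        assert row["formatted"] == "50.0 ± 14.1"

    def test_single_replicate_has_no_plus_minus(self):
        df = stage_summary([self._table(40)])
        assert df[df.gene == "sws1a"].iloc[0]["formatted"] == "40.0"

    def test_missing_gene_treated_as_zero_with_warning(self):
        t1 = self._table(40)
        counts = {"sws1a": 100, "rh2b": 50, "rh1": 50}
        t2 = ExpressionTable.from_counts(counts, {g: 1000.0 for g in counts}, species="sp", stage="adult")
        with pytest.warns(UserWarning, match="missing"):
            df = stage_summary([t1, t2])
        row = df[df.gene == "sws1b"].iloc[0]
        assert row["mean"] == pytest.approx(30.0)  # (60 + 0) / 2


class TestCountsFromAlignments:
    def test_ambiguous_pairs_split_by_unambiguous_ratio(self):
        """Pairs covering no diagnostic SNP are allocated fractionally in
        proportion to the unambiguous totals of each paralog."""
        a = synthio._random_cds(300, np.random.default_rng(3))
        chars = list(a)
        chars[100] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[100]]
        chars[600] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[600]]
        b = "".join(chars)
        from opsinkit.synthio import TranscriptRecord, revcomp

        ra = TranscriptRecord("a", "sp", "sws1a", a, ((0, 900),))
        rb = TranscriptRecord("b", "sp", "sws1b", b, ((0, 900),))
        reads = {
            "pA1": (a[50:200], revcomp(a[150:300])),  # covers SNP 100, allele a
            "pA2": (a[50:200], revcomp(a[200:350])),
            "pB1": (b[550:700], revcomp(b[600:750])),  # covers SNP 600, allele b
            "pAmb": (a[200:350], revcomp(a[300:450])),  # covers no SNP
        }
        hits = phasing.map_reads(reads, None, [ra, rb])
        counts, stats = counts_from_alignments(hits, reads, [ra, rb], [("sws1a", "sws1b")])
        st_ = stats[("sws1a", "sws1b")]
        assert (st_.n_a, st_.n_b, st_.n_ambiguous, st_.n_conflict) == (2, 1, 1, 0)
        # unambiguous reads: a=4, b=2 -> the 2 ambiguous reads split 4/6 vs 2/6
        assert counts["sws1a"] == pytest.approx(4 + 2 * (4 / 6))
        assert counts["sws1b"] == pytest.approx(2 + 2 * (2 / 6))

    def test_simulated_split_recovered_and_reads_conserved(self, repertoire):
        records, _ = repertoire
        pair = [r for r in records if r.gene_label in ("sws1a", "sws1b")]
        r1, r2, _ = synthio.simulate_read_pairs(
            records, {"sws1a": 0.7, "sws1b": 0.3}, 3000, error_rate=0.0, seed=21
        )
        reads = {n: (s1, s2) for (n, s1), (_, s2) in zip(r1, r2)}
        hits = phasing.map_reads(reads, None, pair)
        counts, stats = counts_from_alignments(hits, reads, pair, [("sws1a", "sws1b")])
        st_ = stats[("sws1a", "sws1b")]
        total_reads = counts["sws1a"] + counts["sws1b"]
        assert total_reads == pytest.approx(6000 - 2 * st_.n_conflict, abs=1e-6)
        norm = {g: counts[g] / len(rec) for g, rec in zip(("sws1a", "sws1b"), pair)}
        tot = sum(norm.values())
        assert norm["sws1a"] / tot == pytest.approx(0.7, abs=0.03)

    def test_unique_gene_reads_counted_directly(self, small_library):
        records, reads, manifest = small_library
        hits = phasing.map_reads(reads, None, records)
        counts, _ = counts_from_alignments(hits, reads, records, [("sws1a", "sws1b")])
        # rh1 is unique in this library: every simulated rh1 pair contributes 2 reads
        assert counts["rh1"] == pytest.approx(2 * manifest.realized_pairs["rh1"], rel=0.02)
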