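"""Proportional opsin expression from mapped read counts.

The quantities computed here follow the standard cone-class normalisation
for retinal transcriptomes: mapped read counts R_i are divided by coding
length bp_i, and each gene's length-normalised value is expressed as a
percentage of its cone class total (single cones: sws1/sws2 genes; double
cones: rh2/lws genes). The rod opsin rh1 is expressed as a percentage of
total normalised opsin expression instead:

    R_i,norm = R_i / bp_i
    p_i,SC   = 100 * R_i,norm / T_SC      (i a single-cone opsin)
    p_i,DC   = 100 * R_i,norm / T_DC      (i a double-cone opsin)
    p_rod    = 100 * R_rh1,norm / T_opsins

Reads that map equally well to both members of a low-divergence paralog pair
and cover no diagnostic SNP cannot be phased; discarding them would bias the
pair's totals low, so they are allocated fractionally in proportion to each
paralog's unambiguously assigned read totals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import phasing
from .synthio import TranscriptRecord

__all__ = [
    "SINGLE_CONE",
    "DOUBLE_CONE",
    "ROD",
    "classify_gene",
    "normalize_counts",
    "cone_proportions",
    "rod_proportion",
    "ExpressionTable",
    "counts_from_alignments",
    "stage_summary",
]

SINGLE_CONE = "single_cone"
DOUBLE_CONE = "double_cone"
ROD = "rod"

# Canonical Table-1 column order: single cones, double cones, rod.
GENE_ORDER = ("sws1a", "sws1b", "sws2b", "rh2b", "rh2a_1", "rh2a_2", "lws_1", "lws_2", "rh1")


def classify_gene(gene_label: str) -> str:
    """Cone class of an opsin gene: sws* -> single cone, rh2*/lws* -> double
    cone, rh1 -> rod."""
    g = gene_label.lower()
    if g.startswith("sws"):
        return SINGLE_CONE
    if g.startswith(("rh2", "lws")):
        return DOUBLE_CONE
    if g.startswith("rh1"):
        return ROD
    raise KeyError(f"unknown opsin gene label: {gene_label!r}")


def normalize_counts(counts: Mapping[str, float], lengths: Mapping[str, float]) -> dict[str, float]:
    """Length-normalised counts R_i / bp_i."""
    out = {}
    for g, r in counts.items():
        bp = lengths.get(g)
        if not bp or bp <= 0:
            raise ValueError(f"gene {g!r} has zero or missing length")
        out[g] = r / bp
    return out


def cone_proportions(
    normalized: Mapping[str, float], class_map: Mapping[str, str] | None = None
) -> dict[str, float]:
    """Percent of the cone-class total for every cone opsin (rod excluded).

    Raises if a cone class has members but zero total expression, since its
    proportions would be undefined.
    """
    cm = {g: (class_map[g] if class_map else classify_gene(g)) for g in normalized}
    out: dict[str, float] = {}
    for cls in (SINGLE_CONE, DOUBLE_CONE):
        members = [g for g in normalized if cm[g] == cls]
        if not members:
            continue
        total = sum(normalized[g] for g in members)
        if total <= 0:
            raise ValueError(f"{cls} total is zero; proportions undefined")
        for g in members:
            out[g] = 100.0 * normalized[g] / total
    return out


def rod_proportion(normalized: Mapping[str, float], class_map: Mapping[str, str] | None = None) -> float:
    """Rod opsin percentage of total normalised opsin expression."""
    cm = {g: (class_map[g] if class_map else classify_gene(g)) for g in normalized}
    total = sum(normalized.values())
    if total <= 0:
        raise ValueError("all-zero expression table")
    rod = sum(v for g, v in normalized.items() if cm[g] == ROD)
    return 100.0 * rod / total


@dataclass
class ExpressionTable:
    """Per-gene expression bookkeeping for one individual.

    Holds raw counts, coding lengths, normalised values, cone classes, and
    the class-wise proportions (NaN where a class total is zero).
    """

    counts: dict[str, float]
    lengths: dict[str, float]
    normalized: dict[str, float]
    classes: dict[str, str]
    proportions: dict[str, float]
    p_rod: float
    species: str = ""
    stage: str = ""

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, float],
        lengths: Mapping[str, float],
        class_map: Mapping[str, str] | None = None,
        species: str = "",
        stage: str = "",
    ) -> "ExpressionTable":
        norm = normalize_counts(counts, lengths)
        cm = {g: (class_map[g] if class_map else classify_gene(g)) for g in norm}
        props: dict[str, float] = {}
        for cone_cls in (SINGLE_CONE, DOUBLE_CONE):
            members = [g for g in norm if cm[g] == cone_cls]
            total = sum(norm[g] for g in members)
            for g in members:
                props[g] = 100.0 * norm[g] / total if total > 0 else math.nan
        total_all = sum(norm.values())
        p_rod = (
            100.0 * sum(v for g, v in norm.items() if cm[g] == ROD) / total_all
            if total_all > 0
            else math.nan
        )
        return cls(dict(counts), dict(lengths), norm, cm, props, p_rod, species, stage)

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.counts, key=lambda g: (GENE_ORDER.index(g) if g in GENE_ORDER else 99, g))
        return pd.DataFrame(
            {
                "gene": genes,
                "cone_class": [self.classes[g] for g in genes],
                "reads": [self.counts[g] for g in genes],
                "bp": [self.lengths[g] for g in genes],
                "normalized": [self.normalized[g] for g in genes],
                "proportion_pct": [
                    self.p_rod if self.classes[g] == ROD else self.proportions.get(g, math.nan)
                    for g in genes
                ],
            }
        )


# ---------------------------------------------------------------------------
# Counting mapped pairs, with paralog phasing
# ---------------------------------------------------------------------------


@dataclass
class PhasingStats:
    """Per-paralog-pair phasing outcome counts and the raw partition."""

    n_a: int = 0
    n_b: int = 0
    n_conflict: int = 0
    n_ambiguous: int = 0
    partition: dict[str, str] = field(default_factory=dict)


def counts_from_alignments(
    hits: Sequence[phasing.AlignmentHit],
    reads: Mapping[str, tuple[str, str]],
    references: Sequence[TranscriptRecord],
    paralog_pairs: Sequence[tuple[str, str]] = (),
) -> tuple[dict[str, float], dict[tuple[str, str], PhasingStats]]:
    """Mapped-read counts per gene from alignment hits.

    Each pair is assigned to the gene where its mates align best (fewest
    mismatches + gap bases, most mates mapped). Ties between the two members
    of a declared paralog pair are resolved by SNP phasing: conflicting pairs
    are dropped, ambiguous pairs are later split fractionally in proportion
    to each member's unambiguous totals. Counts are in reads (mapped mates).
    """
    ref_by_label = {r.gene_label: r for r in references}
    paralog_pairs = [tuple(sorted(p)) for p in paralog_pairs]
    pair_of = {a: (a, b) for a, b in paralog_pairs} | {b: (a, b) for a, b in paralog_pairs}
    snps = {
        (a, b): phasing.call_diagnostic_snps(ref_by_label[a].cds, ref_by_label[b].cds)
        for a, b in paralog_pairs
    }

    by_pair: dict[str, dict[str, dict[int, phasing.AlignmentHit]]] = {}
    for h in hits:
        slot = by_pair.setdefault(h.read_id, {}).setdefault(h.gene_label, {})
        prev = slot.get(h.mate)
        if prev is None or h.mismatches + h.gap_bases < prev.mismatches + prev.gap_bases:
            slot[h.mate] = h

    counts: dict[str, float] = {r.gene_label: 0.0 for r in references}
    stats = {pp: PhasingStats() for pp in paralog_pairs}
    deferred: dict[tuple[str, str], list[str]] = {pp: [] for pp in paralog_pairs}

    for pid, by_gene in by_pair.items():
        scored = []
        for label, mates in by_gene.items():
            n_mates = len(mates)
            penalty = sum(h.mismatches + h.gap_bases for h in mates.values())
            scored.append((-n_mates, penalty, label))
        scored.sort()
        best_key = scored[0][:2]
        tied = sorted(lab for nm, pen, lab in scored if (nm, pen) == best_key)
        group = pair_of.get(tied[0])
        if group is not None and set(group) <= set(by_gene):
            # pair maps to both members of a declared paralog pair: phase it
            deferred[group].append(pid)
        elif len(tied) == 1:
            counts[tied[0]] += len(by_gene[tied[0]])
        else:
            # unrelated tie: deterministic first-label assignment
            counts[tied[0]] += len(by_gene[tied[0]])

    for (a, b), pids in deferred.items():
        if not pids:
            continue
        sub_hits = [
            h
            for pid in pids
            for g in (a, b)
            for h in by_pair[pid].get(g, {}).values()
        ]
        partition = phasing.phase_read_pairs(sub_hits, reads, snps[(a, b)], a, b)
        st = stats[(a, b)]
        st.partition = partition
        amb_reads = 0.0
        for pid in pids:
            n_mates = max(len(by_pair[pid].get(a, {})), len(by_pair[pid].get(b, {})))
            call = partition.get(pid, "ambiguous")
            if call == "A":
                counts[a] += n_mates
                st.n_a += 1
            elif call == "B":
                counts[b] += n_mates
                st.n_b += 1
            elif call == "conflict":
                st.n_conflict += 1
            else:
                amb_reads += n_mates
                st.n_ambiguous += 1
        tot = counts[a] + counts[b]
        fa = counts[a] / tot if tot > 0 else 0.5
        counts[a] += amb_reads * fa
        counts[b] += amb_reads * (1 - fa)
    return counts, stats


# ---------------------------------------------------------------------------
# Table-1-style summaries
# ---------------------------------------------------------------------------


def _fmt(mean: float, sd: float | None) -> str:
    if math.isnan(mean):
        return ""
    if sd is None:
        return f"{mean:.1f}"
    return f"{mean:.1f} ± {sd:.1f}"


def stage_summary(tables: Sequence[ExpressionTable]) -> pd.DataFrame:
    """Mean +- sample sd of each gene's proportion per (species, stage) group.

    Returns a tidy frame with numeric mean/sd/n and a formatted one-decimal
    string per cell; single-replicate groups report the mean without +-.
    Genes missing from a replicate are treated as 0 with a warning.
    """
    if not tables:
        raise ValueError("no expression tables given")
    groups: dict[tuple[str, str], list[ExpressionTable]] = {}
    for t in tables:
        groups.setdefault((t.species, t.stage), []).append(t)
    rows = []
    for (species, stage), reps in groups.items():
        genes = sorted(
            {g for t in reps for g in t.counts},
            key=lambda g: (GENE_ORDER.index(g) if g in GENE_ORDER else 99, g),
        )
        for g in genes:
            vals = []
            for t in reps:
                if g not in t.counts:
                    warnings.warn(f"gene {g} missing from a replicate of {species}/{stage}; treated as 0")
                    vals.append(0.0)
                else:
                    vals.append(t.p_rod if t.classes[g] == ROD else t.proportions.get(g, math.nan))
            arr = np.asarray(vals, dtype=float)
            mean = float(np.nanmean(arr)) if not np.all(np.isnan(arr)) else math.nan
            sd = float(np.nanstd(arr, ddof=1)) if len(arr) > 1 else None
            rows.append(
                {
                    "species": species,
                    "stage": stage,
                    "gene": g,
                    "cone_class": classify_gene(g),
                    "mean": mean,
                    "sd": math.nan if sd is None else sd,
                    "n": len(arr),
                    "formatted": _fmt(mean, sd),
                }
            )
    return pd.DataFrame(rows)
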