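"""Gene-conversion segment detection and exon-wise phylogenetic signal.

Gene conversion between recently duplicated opsin paralogs homogenizes
stretches of their coding regions, pulling a sequence toward the wrong
clade over the converted interval. This module detects such segments with a
sliding-window nearest-clade profile: within each window a query's identity
to each clade's consensus is computed, and maximal runs of windows where the
nearest clade differs from the query's expected clade become conversion
segments with breakpoints at the run boundaries. This is an identity-based
stand-in for likelihood recombination scanners — same qualitative output
(breakpoints plus per-domain ancestry) at desk scale.

``exon_signal`` ranks exons by ortholog-discriminating signal (mean
between-clade minus mean within-clade p-distance over the exon's columns),
the quantity that motivates restricting paralog phylogenies to the exons
least affected by conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["WindowProfile", "ConversionSegment", "ExonSignal", "window_profiles", "detect_breakpoints", "exon_signal"]

_GAP = ord("-")


@dataclass
class WindowProfile:
    """Per-window identities to each clade consensus and nearest-clade labels.

    ``identities[query][clade]`` is an array over windows (NaN where the
    window had no comparable columns); ``nearest[query]`` holds the
    per-window nearest clade (None for flagged/skipped windows).
    """

    windows: list[tuple[int, int]]
    clades: list[str]
    identities: dict[str, dict[str, np.ndarray]]
    nearest: dict[str, list[str | None]]
    #: per query and clade: column-wise "query matches this clade's consensus"
    matches: dict[str, dict[str, np.ndarray]]
    #: per query and clade: column-wise "both query and consensus are non-gap"
    comparable: dict[str, dict[str, np.ndarray]]
    n_columns: int = 0


@dataclass(frozen=True)
class ConversionSegment:
    query: str
    start: int
    end: int
    donor: str
    support: int


@dataclass(frozen=True)
class ExonSignal:
    exon: tuple[int, int]
    score: float
    rank: int


def _msa_arrays(msa) -> dict[str, np.ndarray]:
    items = list(msa.items()) if isinstance(msa, Mapping) else list(msa)
    if not items:
        raise ValueError("empty alignment")
    L = len(items[0][1])
    out = {}
    for name, seq in items:
        if len(seq) != L:
            raise ValueError(f"{name}: alignment rows differ in length")
        out[name] = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    return out


def _clade_consensus(arrays: Mapping[str, np.ndarray], members: Sequence[str]) -> np.ndarray:
    """Column-wise majority base (ties broken by byte order; all-gap -> gap)."""
    stack = np.stack([arrays[m] for m in members])
    L = stack.shape[1]
    cons = np.empty(L, dtype=np.uint8)
    alphabet = np.unique(stack)
    counts = np.stack([(stack == a).sum(axis=0) for a in alphabet])
    nongap = alphabet != _GAP
    if nongap.any():
        sub = counts[nongap]
        best = sub.argmax(axis=0)
        cons = alphabet[nongap][best]
        cons = np.where(sub.max(axis=0) == 0, _GAP, cons)
    else:
        cons[:] = _GAP
    return cons


def window_profiles(
    msa,
    clade_labels: Mapping[str, str],
    window: int = 90,
    step: int = 15,
) -> WindowProfile:
    """Sliding-window identity of every labeled sequence to each clade consensus.

    Windows of ``window`` columns every ``step`` columns; gap columns (in the
    query or the consensus) are excluded from each identity denominator, and
    windows with no comparable columns are flagged as skipped (None). When a
    query is scored against its own clade the consensus is computed without
    it (leave-one-out), unless it is its clade's only member.
    """
    if window < 30:
        raise ValueError("window must be >= 30 columns")
    arrays = _msa_arrays(msa)
    L = len(next(iter(arrays.values())))
    if L < window:
        raise ValueError(f"alignment length {L} shorter than one window ({window})")
    clades = sorted(set(clade_labels.values()))
    members = {c: [q for q, cl in clade_labels.items() if cl == c] for c in clades}
    windows = [(s, s + window) for s in range(0, L - window + 1, step)]

    identities: dict[str, dict[str, np.ndarray]] = {}
    nearest: dict[str, list[str | None]] = {}
    matches: dict[str, dict[str, np.ndarray]] = {}
    comparable: dict[str, dict[str, np.ndarray]] = {}
    cons_all = {c: _clade_consensus(arrays, members[c]) for c in clades}
    for q in clade_labels:
        qarr = arrays[q]
        ids = {c: np.full(len(windows), np.nan) for c in clades}
        matches[q] = {}
        comparable[q] = {}
        for c in clades:
            others = [m for m in members[c] if m != q]
            cons = _clade_consensus(arrays, others) if others else cons_all[c]
            comp = (qarr != _GAP) & (cons != _GAP)
            match = comp & (qarr == cons)
            matches[q][c] = match
            comparable[q][c] = comp
            ccomp = np.concatenate([[0], np.cumsum(comp)])
            cmatch = np.concatenate([[0], np.cumsum(match)])
            for w, (s, e) in enumerate(windows):
                denom = ccomp[e] - ccomp[s]
                if denom > 0:
                    ids[c][w] = (cmatch[e] - cmatch[s]) / denom
        near: list[str | None] = []
        prev: str | None = None
        for w in range(len(windows)):
            vals = {c: ids[c][w] for c in clades if not np.isnan(ids[c][w])}
            if not vals:
                near.append(None)  # all-gap window: flagged, skipped
                continue
            top = max(vals.values())
            tied = sorted(c for c, v in vals.items() if v == top)
            if len(tied) == 1:
                choice = tied[0]
            elif prev in tied:
                choice = prev  # ties inherit the previous window's label
            else:
                # tie with no informative predecessor: uninformative window
                near.append(None)
                continue
            near.append(choice)
            prev = choice
        identities[q] = ids
        nearest[q] = near
    return WindowProfile(windows, clades, identities, nearest, matches, comparable, L)


def _refine_boundaries(
    profile: WindowProfile, q: str, exp: str, donor: str, ws: int, we: int
) -> tuple[int, int]:
    """Snap a run's window-resolution boundaries to informative sites.

    The true breakpoint is unidentifiable between the last expected-clade
    site and the first donor site (and symmetrically at the other end), so
    each boundary is placed at the midpoint of that gap. A boundary with no
    flanking expected-clade site extends to the alignment edge.
    """
    mE, mD = profile.matches[q][exp], profile.matches[q][donor]
    comp = profile.comparable[q][exp] & profile.comparable[q][donor]
    informative = comp & (mE ^ mD)
    donor_sites = np.flatnonzero(informative & mD)
    exp_sites = np.flatnonzero(informative & mE)
    inside = donor_sites[(donor_sites >= ws) & (donor_sites < we)]
    if inside.size == 0:
        return ws, we
    d0, d1 = int(inside[0]), int(inside[-1])
    before = exp_sites[exp_sites < d0]
    after = exp_sites[exp_sites > d1]
    start = (int(before[-1]) + d0) // 2 + 1 if before.size else 0
    end = (d1 + int(after[0])) // 2 + 1 if after.size else profile.n_columns
    return start, end


def detect_breakpoints(
    profile: WindowProfile,
    expected_clade: Mapping[str, str],
    min_run: int = 2,
    refine: bool = True,
) -> list[ConversionSegment]:
    """Conversion segments: maximal runs of >= ``min_run`` consecutive windows
    whose nearest clade differs from the query's expected clade.

    The donor is the observed nearest clade. With ``refine`` (default) each
    run's boundaries are snapped from window resolution to the midpoint of
    the informative-site gap flanking the run; otherwise segments span from
    the first to the last window of the run (alignment columns, half-open).
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    segments: list[ConversionSegment] = []
    for q in sorted(expected_clade):
        if q not in profile.nearest:
            raise KeyError(f"query {q!r} absent from profile")
        exp = expected_clade[q]
        near = profile.nearest[q]
        i = 0
        while i < len(near):
            lab = near[i]
            if lab is None or lab == exp:
                i += 1
                continue
            j = i
            while j < len(near) and near[j] == lab:
                j += 1
            if j - i >= min_run:
                ws, we = profile.windows[i][0], profile.windows[j - 1][1]
                if refine:
                    ws, we = _refine_boundaries(profile, q, exp, lab, ws, we)
                segments.append(ConversionSegment(q, ws, we, lab, j - i))
            i = j
    return segments


def _pdistance_matrix(arrays: Mapping[str, np.ndarray], names: Sequence[str], cols: slice) -> np.ndarray:
    """Pairwise p-distances over non-gap column pairs within ``cols``."""
    n = len(names)
    sub = {m: arrays[m][cols] for m in names}
    d = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = sub[names[i]], sub[names[j]]
            comp = (x != _GAP) & (y != _GAP)
            ncomp = int(comp.sum())
            if ncomp:
                d[i, j] = d[j, i] = int(((x != y) & comp).sum()) / ncomp
    return d


def exon_signal(
    msa,
    exon_intervals: Sequence[tuple[int, int]],
    clade_labels: Mapping[str, str],
) -> list[ExonSignal]:
    """Rank exons by ortholog-discriminating signal.

    Score = mean between-clade p-distance minus mean within-clade p-distance
    over the exon's alignment columns; exons are returned ranked descending.
    """
    arrays = _msa_arrays(msa)
    names = sorted(clade_labels)
    clades = [clade_labels[n] for n in names]
    if len(set(clades)) < 2:
        raise ValueError("need at least two clades to measure between-clade signal")
    results = []
    for exon in exon_intervals:
        s, e = exon
        d = _pdistance_matrix(arrays, names, slice(s, e))
        between, within = [], []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if np.isnan(d[i, j]):
                    continue
                (between if clades[i] != clades[j] else within).append(d[i, j])
        if not between:
            raise ValueError(f"exon {exon} has no comparable between-clade columns")
        score = float(np.mean(between)) - (float(np.mean(within)) if within else 0.0)
        results.append((exon, score))
    order = sorted(range(len(results)), key=lambda i: -results[i][1])
    ranked = [None] * len(results)
    for rank, i in enumerate(order, start=1):
        exon, score = results[i]
        ranked[i] = ExonSignal(tuple(exon), score, rank)
    return sorted(ranked, key=lambda r: -r.score)


def write_segments_tsv(segments: Iterable[ConversionSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tstart\tend\tdonor\tsupport\n")
        for s in segments:
            fh.write(f"{s.query}\t{s.start}\t{s.end}\t{s.donor}\t{s.support}\n")


def write_segments_bed(segments: Iterable[ConversionSegment], path: str | Path, name: str = "alignment") -> None:
    """BED-like intervals of conversion segments in alignment coordinates."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{name}\t{s.start}\t{s.end}\t{s.query}|donor={s.donor}\t{s.support}\n")
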