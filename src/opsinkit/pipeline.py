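"""End-to-end orchestration: simulate -> map -> phase -> quantify -> classify -> scan.

A run is described by a plain-text (YAML) config holding either real input
paths or a simulation block, never both. All seeds are explicit in the
config and recorded in the run manifest; two runs from the same config
produce byte-identical tables. Every output table carries a header comment
naming the pipeline version and the config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import convscan, quant, tuning
from .phasing import MapParams, load_read_pairs, map_reads
from .quant import ExpressionTable, counts_from_alignments, stage_summary
from .synthio import (
    GENE_LABELS,
    ConversionTract,
    TranscriptRecord,
    make_repertoire,
    read_fasta,
    simulate_read_pairs,
    write_fasta,
)

__version__ = "0.1.0"

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_PARALOG_PAIRS = (("sws1a", "sws1b"), ("rh2a_1", "rh2a_2"), ("lws_1", "lws_2"))


@dataclass
class RunConfig:
    """Validated run configuration.

    Exactly one of ``inputs`` (real data paths) or ``simulate`` (synthetic
    block) must be present. The simulation block lists species, their stage
    proportions and replicate counts, plus library parameters.
    """

    outdir: Path
    seed: int
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None
    uv_patterns: Path | None = None
    overrides: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: Mapping[str, Any]) -> RunConfig:
    return RunConfig(
        outdir=Path(raw.get("outdir", "opsinkit_out")),
        seed=int(raw.get("seed", 0)),
        simulate=raw.get("simulate"),
        inputs=raw.get("inputs"),
        uv_patterns=Path(raw["uv_patterns"]) if raw.get("uv_patterns") else None,
        overrides=dict(raw.get("overrides", {})),
        raw=dict(raw),
    )


def _header(config: RunConfig) -> str:
    return f"# opsinkit {__version__} config={config.config_hash}\n"


def _write_table(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def parse_gene_label(name: str) -> str:
    """Gene label from a FASTA id: either the id itself or its suffix after
    the species prefix (e.g. ``synthetic_rh2a_1`` -> ``rh2a_1``)."""
    if name in GENE_LABELS:
        return name
    if "_" in name:
        suffix = name.split("_", 1)[1]
        if suffix in GENE_LABELS:
            return suffix
    return name


def _run_real(config: RunConfig) -> Path:
    """Quantify externally supplied FASTQ libraries against reference CDSs."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    inputs = config.inputs
    refs = [
        TranscriptRecord(name, "input", parse_gene_label(name), seq, ((0, len(seq)),))
        for name, seq in read_fasta(inputs["references"])
    ]
    labels = {r.gene_label for r in refs}
    pairs_here = [p for p in _PARALOG_PAIRS if set(p) <= labels]
    lengths = {r.gene_label: float(len(r)) for r in refs}
    map_params = MapParams(**config.overrides.get("mapping", {}))
    tables: list[ExpressionTable] = []
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "libraries": [],
    }
    for i, lib in enumerate(inputs["libraries"]):
        reads = load_read_pairs(lib["r1"], lib["r2"])
        hits = map_reads(reads, None, refs, map_params)
        counts, _ = counts_from_alignments(hits, reads, refs, pairs_here)
        tab = ExpressionTable.from_counts(
            counts, lengths, species=lib.get("species", ""), stage=lib.get("stage", "")
        )
        tables.append(tab)
        name = f"{tab.species or 'lib'}_{tab.stage or i}_rep{i + 1}_expression.tsv"
        _write_table(tab.to_frame(), out / name, config)
        manifest["libraries"].append({"species": tab.species, "stage": tab.stage, "n_reads": 2 * len(reads)})
    _write_table(stage_summary(tables), out / "stage_summary.tsv", config)
    calls = [tuning.call_sws1(r.cds, r.gene_label) for r in refs if r.gene_label.startswith("sws1")]
    tuning.write_calls_tsv(calls, out / "tuning_calls.tsv")
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run and return the output directory.

    Writes per-individual expression TSVs, a stage summary, SWS1 tuning
    calls, conversion segments and exon ranks, a join of dual-sws1
    expression flags against UV-pattern annotations (if provided), and a
    machine-readable run manifest.
    """
    if config.simulate is None:
        return _run_real(config)
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulate
    n_pairs = int(sim.get("n_pairs", 20000))
    read_len = int(sim.get("read_len", 150))
    insert = tuple(sim.get("insert", (250, 300)))
    error_rate = float(sim.get("error_rate", 0.001))
    divergence = float(sim.get("divergence", 0.01))
    map_params = MapParams(**config.overrides.get("mapping", {}))
    species_blocks = sim["species"]

    tables: list[ExpressionTable] = []
    tuning_calls: list[tuning.BrhSiteCall] = []
    sws1_alignment: dict[str, str] = {}
    sws1_clades: dict[str, str] = {}
    dual_sws1: dict[str, bool] = {}
    manifest: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash,
        "seed": config.seed,
        "species": {},
    }

    sp_seeds = _child_seeds(config.seed, len(species_blocks))
    for sp_seed, block in zip(sp_seeds, species_blocks):
        name = block["name"]
        tract_spec = [
            ConversionTract(int(t["start"]), int(t["end"]), t.get("donor", "a"))
            for t in block.get("sws1_tracts", [])
        ]
        labels = tuple(block.get("genes") or next(iter(block["stages"].values()))["proportions"])
        repertoire, _diag = make_repertoire(
            sp_seed, labels=labels, species=name, divergence=divergence,
            tracts={"sws1": tract_spec} if tract_spec else None,
        )
        write_fasta(repertoire, out / f"{name}_repertoire.fasta")
        by_label = {r.gene_label: r for r in repertoire}
        pairs_here = [p for p in _PARALOG_PAIRS if set(p) <= set(by_label)]
        lengths = {r.gene_label: float(len(r)) for r in repertoire}
        manifest["species"][name] = {"seed": sp_seed, "libraries": []}

        lib_idx = 0
        for stage, stage_block in block["stages"].items():
            props = {g: float(p) for g, p in stage_block["proportions"].items()}
            for rep in range(int(stage_block.get("replicates", 1))):
                lib_seed = _child_seeds(sp_seed, 100)[lib_idx]
                lib_idx += 1
                r1, r2, truth = simulate_read_pairs(
                    repertoire, props, n_pairs, read_len, insert, error_rate, lib_seed
                )
                reads = {n: (s1, s2) for (n, s1), (_, s2) in zip(r1, r2)}
                hits = map_reads(reads, None, repertoire, map_params)
                counts, _stats = counts_from_alignments(hits, reads, repertoire, pairs_here)
                tab = ExpressionTable.from_counts(counts, lengths, species=name, stage=stage)
                tables.append(tab)
                _write_table(tab.to_frame(), out / f"{name}_{stage}_rep{rep + 1}_expression.tsv", config)
                manifest["species"][name]["libraries"].append(
                    {"stage": stage, "replicate": rep + 1, "seed": lib_seed, "n_pairs": truth.n_pairs}
                )

        for lab in ("sws1a", "sws1b"):
            if lab in by_label:
                tuning_calls.append(tuning.call_sws1(by_label[lab].cds, f"{name}_{lab}"))
                sws1_alignment[f"{name}_{lab}"] = by_label[lab].cds
                sws1_clades[f"{name}_{lab}"] = "alpha" if lab == "sws1a" else "beta"
        dual_sws1[name] = "sws1a" in by_label and "sws1b" in by_label

    summary = stage_summary(tables)
    _write_table(summary, out / "stage_summary.tsv", config)

    calls_df = pd.DataFrame(
        [
            {
                "gene": c.gene_label,
                "res114": c.residue_114,
                "res118": c.residue_118,
                "phenotype": c.phenotype,
                "lambda_max_nm": c.lambda_max_nm,
            }
            for c in tuning_calls
        ]
    )
    _write_table(calls_df, out / "tuning_calls.tsv", config)

    seg_rows: list[dict[str, Any]] = []
    exon_rows: list[dict[str, Any]] = []
    lengths_set = {len(s) for s in sws1_alignment.values()}
    if len(sws1_alignment) >= 4 and len(lengths_set) == 1 and len(set(sws1_clades.values())) == 2:
        profile = convscan.window_profiles(sws1_alignment, sws1_clades)
        segments = convscan.detect_breakpoints(profile, sws1_clades)
        seg_rows = [
            {"query": s.query, "start": s.start, "end": s.end, "donor": s.donor, "support": s.support}
            for s in segments
        ]
        exon_ref = next(iter(sws1_alignment))
        L = len(sws1_alignment[exon_ref])
        exons = [(round(f0 * L), round(f1 * L)) for f0, f1 in zip((0, 0.30, 0.55, 0.80), (0.30, 0.55, 0.80, 1.0))]
        for sig in convscan.exon_signal(sws1_alignment, exons, sws1_clades):
            exon_rows.append({"exon_start": sig.exon[0], "exon_end": sig.exon[1], "score": sig.score, "rank": sig.rank})
    _write_table(pd.DataFrame(seg_rows, columns=["query", "start", "end", "donor", "support"]), out / "conversion_segments.tsv", config)
    _write_table(pd.DataFrame(exon_rows, columns=["exon_start", "exon_end", "score", "rank"]), out / "exon_ranks.tsv", config)

    # Dual-sws1 expression flags joined with visually scored UV patterns.
    join_rows = []
    annotations: dict[str, str] = {}
    if config.uv_patterns is not None:
        ann = pd.read_csv(config.uv_patterns, sep="\t", comment="#")
        for _, row in ann.iterrows():
            annotations[str(row["species"])] = str(row["pattern"])
    for name, dual in sorted(dual_sws1.items()):
        join_rows.append(
            {"species": name, "dual_sws1": dual, "uv_pattern": annotations.get(name, "unscored")}
        )
    _write_table(pd.DataFrame(join_rows), out / "sws1_uv_join.tsv", config)

    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
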