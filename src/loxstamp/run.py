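"""End-to-end orchestration: simulate -> call -> filter -> link.

All randomness flows from one top-level seed through named per-stage
substreams, so identical configs and seeds reproduce every output byte for
byte.  Each stage writes plain-text outputs into the run directory and the
manifest records their checksums.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, frequency, io, linkage
from .cassette import CassetteDesign
from .simulate import SimConfig, simulate_experiment

log = logging.getLogger("loxstamp")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream: a deterministic generator per (seed, stage name)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    sub = int.from_bytes(digest[:4], "little") & 0x7FFFFFFF
    return np.random.default_rng(sub)


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for a full pipeline run."""

    out_dir: str
    seed: int = 0
    design: dict = field(default_factory=dict)  # CassetteDesign.generate kwargs
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    min_reads: int = 30
    cb_max_edits: int = 8
    cutoff: float = 0.005
    n_perm: int = 1000
    stages: tuple[str, ...] = ("simulate", "call", "filter", "link")
    lineages_path: str | None = None  # external labels; default: simulated truth

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = io.read_json(path)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def calling_params(self) -> calling.CallingParams:
        return calling.CallingParams(
            min_reads=self.min_reads, cb_max_edits=self.cb_max_edits
        )


def _echo_thresholds(config: RunConfig) -> None:
    log.info(
        "[config] seed=%d min_reads=%d cb_max_edits=%d cutoff=%g n_perm=%d",
        config.seed,
        config.min_reads,
        config.cb_max_edits,
        config.cutoff,
        config.n_perm,
    )


def run_all(config: RunConfig) -> Path:
    """Execute the requested stages in order; returns the output directory.

    Any stage failure aborts with the stage name attached to the exception.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_thresholds(config)
    produced: dict[str, list[str]] = {}
    stage = "setup"
    try:
        design = CassetteDesign.generate(**config.design)
        io.write_fasta(design.reference_sequences(), out / "blocks.fa")
        io.write_json(design.to_dict(), out / "design.json")
        produced["setup"] = ["blocks.fa", "design.json"]

        if "simulate" in config.stages:
            stage = "simulate"
            sim_config = SimConfig.from_dict(config.sim) if config.sim else SimConfig()
            truth, reads = simulate_experiment(
                sim_config, design, stage_rng(config.seed, "simulate")
            )
            io.write_fastq(reads, out / "reads.fastq")
            io.write_tsv(truth.founders, out / "truth_founders.tsv")
            io.write_tsv(truth.cells, out / "truth_cells.tsv")
            io.write_tsv(truth.reads, out / "truth_reads.tsv")
            io.write_tsv(truth.cell_whitelist(), out / "whitelist_cells.tsv")
            uci_wl = truth.founders[["uci"]].drop_duplicates().sort_values("uci")
            io.write_tsv(uci_wl, out / "whitelist_uci.tsv")
            produced["simulate"] = [
                "reads.fastq",
                "truth_founders.tsv",
                "truth_cells.tsv",
                "truth_reads.tsv",
                "whitelist_cells.tsv",
                "whitelist_uci.tsv",
            ]

        if "call" in config.stages:
            stage = "call"
            reads = io.read_fastq(out / "reads.fastq")
            reference = io.read_fasta(out / "blocks.fa")
            wl = io.read_tsv(
                out / "whitelist_cells.tsv",
                required=("cell_id", "barcode", "upstream", "downstream"),
            )
            whitelist = [
                calling.CellBarcodeRef(r.cell_id, r.barcode, r.upstream, r.downstream)
                for r in wl.itertuples()
            ]
            uci_whitelist = set(
                io.read_tsv(out / "whitelist_uci.tsv", required=("uci",))["uci"]
            )
            calls = calling.call_timestamps(
                reads, reference, whitelist, uci_whitelist, config.calling_params()
            )
            io.write_tsv(calls, out / "cell_calls.tsv")
            produced["call"] = ["cell_calls.tsv"]

        if "filter" in config.stages:
            stage = "filter"
            calls = io.read_tsv(out / "cell_calls.tsv", required=("cell_id",))
            retained, report = frequency.filter_high_frequency(
                calls, cutoff=config.cutoff
            )
            io.write_tsv(retained, out / "cell_calls.filtered.tsv")
            io.write_tsv(report, out / "frequency_report.tsv")
            produced["filter"] = ["cell_calls.filtered.tsv", "frequency_report.tsv"]

        if "link" in config.stages:
            stage = "link"
            retained = io.read_tsv(out / "cell_calls.filtered.tsv", required=("cell_id",))
            if config.lineages_path is not None:
                lin_path = Path(config.lineages_path)
            else:
                lin_path = out / "truth_cells.tsv"
            if not lin_path.exists():
                raise FileNotFoundError(f"lineage table not found: {lin_path}")
            lin = io.read_tsv(lin_path, required=("cell_id", "lineage"))
            annotated = linkage.join_lineages(retained, lin)
            edges = linkage.build_linkage_edges(annotated)
            io.write_tsv(edges, out / "edges.tsv")
            matrix = linkage.lineage_barcode_matrix(annotated)
            if matrix.shape[1] >= 2:
                corr = linkage.lineage_correlation(matrix)
                corr.index.name = "lineage"
                corr.reset_index().to_csv(
                    out / "lineage_correlation.tsv", sep="\t", index=False
                )
            enrich = linkage.sharing_enrichment(
                annotated, n_perm=config.n_perm, rng=stage_rng(config.seed, "link")
            )
            io.write_tsv(enrich, out / "enrichment.tsv")
            produced["link"] = ["edges.tsv", "enrichment.tsv"] + (
                ["lineage_correlation.tsv"] if matrix.shape[1] >= 2 else []
            )
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    meta = {
        "seed": config.seed,
        "thresholds": {
            "min_reads": config.min_reads,
            "cb_max_edits": config.cb_max_edits,
            "cutoff": config.cutoff,
            "n_perm": config.n_perm,
        },
        "stages": list(config.stages),
    }
    io.write_manifest(out, produced, meta)
    return out
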