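"""Ground-truthed synthetic timestamp-barcoding experiments.

Emulates the wet-lab design end to end: founder ESCs each carry a single
integrated cassette (low-MOI, one integration per cell) with a static 10-nt UCI
drawn from a skewed library; Cre induction at day 0 (before lineage commitment)
or day 8 (after the PGC-like lineage has committed) fixes each founder's
Polylox arrangement; founders expand clonally into embryoid-body lineages;
sampled cells are read out by nanopore-like long reads carrying a cell-barcode
construct, with substitution/insertion/deletion errors, 3'-truncation and
cell-barcode cross-contamination.

Truth never leaks through sequence identifiers: read ids are opaque and the
ground truth lives only in the returned tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cassette import (
    CassetteDesign,
    SpanBias,
    barcode_string,
    intact_state,
    render_sequence,
    revcomp,
    simulate_recombination,
)

#: terminal embryoid-body populations scored at day 14
LINEAGES = ("EN", "S.Ect", "MES", "BP", "PGC")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment."""

    n_founders: int = 1000
    uci_library_size: int = 5000
    uci_skew: float = 1.0
    induction_time: str = "day0"  # "day0" | "day8"
    lineage_proportions: dict = field(
        default_factory=lambda: {
            "EN": 0.25,
            "S.Ect": 0.20,
            "MES": 0.30,
            "BP": 0.13,
            "PGC": 0.12,
        }
    )
    committed_lineages: tuple[str, ...] = ("PGC",)
    expansion_per_founder: int = 50
    cells_sampled: int | None = None  # None -> keep every expanded cell
    reads_per_cell_mean: float = 50.0
    reads_per_cell_dispersion: float | None = 10.0  # NB size; None -> exact count
    sub_rate: float = 0.02
    ins_rate: float = 0.03
    del_rate: float = 0.04
    truncation_prob: float = 0.1
    contamination_rate: float = 0.02
    amplicon_size_window: tuple[int, int] = (700, 2500)
    recombination_lambda: float = 2.0
    bias_beta: float = 1.0
    unique_founder_ucis: bool = True
    cell_barcode_length: int = 12
    cb_flank_upstream_length: int = 20
    cb_flank_downstream_length: int = 24
    cb_min_pairwise_edits: int = 4

    def __post_init__(self) -> None:
        if self.induction_time not in ("day0", "day8"):
            raise ValueError("induction_time must be 'day0' or 'day8'")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")
        if not self.lineage_proportions:
            raise ValueError("lineage set must be non-empty")
        total = sum(self.lineage_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"lineage proportions must sum to 1, got {total}")
        for name, rate in (
            ("sub_rate", self.sub_rate),
            ("ins_rate", self.ins_rate),
            ("del_rate", self.del_rate),
            ("truncation_prob", self.truncation_prob),
            ("contamination_rate", self.contamination_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["lineage_proportions"] = dict(self.lineage_proportions)
        d["committed_lineages"] = list(self.committed_lineages)
        d["amplicon_size_window"] = list(self.amplicon_size_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "committed_lineages" in d:
            d["committed_lineages"] = tuple(d["committed_lineages"])
        if "amplicon_size_window" in d:
            d["amplicon_size_window"] = tuple(d["amplicon_size_window"])
        return cls(**d)


@dataclass
class SimTruth:
    """Ground-truth tables for one simulated experiment."""

    founders: pd.DataFrame  # founder_id, uci, polylox, committed_lineage
    cells: pd.DataFrame  # cell_id, cell_barcode, founder_id, lineage
    reads: pd.DataFrame  # read_id, origin_cell, assigned_cell, strand, trunc
    cb_flank_upstream: str = ""
    cb_flank_downstream: str = ""

    def cell_whitelist(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cells["cell_id"],
                "barcode": self.cells["cell_barcode"],
                "upstream": self.cb_flank_upstream,
                "downstream": self.cb_flank_downstream,
            }
        )

    def perfect_calls(self) -> pd.DataFrame:
        """Truth-derived cell-call table (as if calling recovered every cell).

        Lets the frequency filter and linkage statistics run directly on
        simulated ground truth, isolating them from read-level recovery.
        """
        merged = self.cells.merge(self.founders, on="founder_id")
        return pd.DataFrame(
            {
                "cell_id": merged["cell_id"],
                "polylox": merged["polylox"],
                "uci": merged["uci"],
                "timestamp": merged["polylox"] + ":" + merged["uci"],
                "n_reads_cell": 0,
                "n_reads_polylox_top": 0,
                "n_reads_uci_top": 0,
                "pass_polylox": True,
                "pass_uci": True,
                "fail_reasons": "",
            }
        )


def _int_to_kmer(values: np.ndarray, length: int) -> list[str]:
    out = []
    for v in values:
        chars = []
        for _ in range(length):
            v, r = divmod(int(v), 4)
            chars.append("ACGT"[r])
        out.append("".join(chars))
    return out


def draw_uci_library(
    size: int, skew: float, rng: np.random.Generator, length: int = 10
) -> pd.DataFrame:
    """Distinct random UCIs with log-normal abundance weights (sigma = skew)."""
    if size > 4**length:
        raise ValueError(f"cannot draw {size} distinct {length}-mers")
    if skew < 0:
        raise ValueError("skew must be >= 0")
    codes = rng.choice(4**length, size=size, replace=False)
    weights = rng.lognormal(mean=0.0, sigma=skew, size=size)
    weights = weights / weights.sum()
    return pd.DataFrame({"uci": _int_to_kmer(codes, length), "weight": weights})


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _cell_barcodes(
    n: int, length: int, rng: np.random.Generator, min_edits: int, enforce: bool
) -> list[str]:
    """Distinct cell barcodes; pairwise edit distance enforced when reads are made."""
    if enforce:
        import edlib

        accepted: list[str] = []
        while len(accepted) < n:
            cand = _random_seq(rng, length)
            if all(
                edlib.align(cand, prev, mode="NW", k=min_edits - 1)["editDistance"]
                == -1
                for prev in accepted
            ):
                accepted.append(cand)
        return accepted
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        cand = _random_seq(rng, length)
        if cand not in seen:
            seen.add(cand)
            out.append(cand)
    return out


def mutate_read(
    seq: str,
    sub_rate: float,
    ins_rate: float,
    del_rate: float,
    truncation_prob: float,
    rng: np.random.Generator,
) -> tuple[str, str, int | None]:
    """Apply per-base noise and optional 3'-truncation.

    Per input base: an insertion before it with ``ins_rate``, deletion with
    ``del_rate``, otherwise a strict substitution with ``sub_rate``.  With
    ``truncation_prob`` the read is cut at a uniform position (prefix kept),
    emulating sequencing truncation.  Returns (sequence, placeholder quality,
    truncation point or None).
    """
    for name, rate in (("sub", sub_rate), ("ins", ins_rate), ("del", del_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} rate must be in [0, 1]")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n = arr.size
    if n:
        sub_mask = rng.random(n) < sub_rate
        if sub_mask.any():
            idx = _BASE_INDEX[arr[sub_mask]]
            arr[sub_mask] = _BASES[
                (idx + rng.integers(1, 4, size=int(sub_mask.sum()))) % 4
            ]
        keep = rng.random(n) >= del_rate
        ins_mask = rng.random(n) < ins_rate
        counts = ins_mask.astype(np.int64) + keep.astype(np.int64)
        out = np.empty(int(counts.sum()), dtype=np.uint8)
        ends = np.cumsum(counts)
        starts = ends - counts
        if ins_mask.any():
            out[starts[ins_mask]] = _BASES[
                rng.integers(0, 4, size=int(ins_mask.sum()))
            ]
        out[ends[keep] - 1] = arr[keep]
        arr = out
    trunc: int | None = None
    if arr.size > 1 and rng.random() < truncation_prob:
        trunc = int(rng.integers(1, arr.size))
        arr = arr[:trunc]
    mutated = arr.tobytes().decode()
    return mutated, "I" * len(mutated), trunc


def contaminate(
    reads: pd.DataFrame,
    rate: float,
    rng: np.random.Generator,
    cell_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Reassign each read's cell barcode to a different cell with probability ``rate``.

    Operates on the read plan (column ``assigned_cell``); the ``origin_cell``
    column is untouched so the truth table still records the real origin.
    """
    if not 0.0 <= rate < 1.0 + 1e-12:
        raise ValueError("rate must be in [0, 1]")
    out = reads.copy()
    if rate == 0.0 or out.empty:
        return out
    cells = list(cell_ids) if cell_ids is not None else sorted(out["origin_cell"].unique())
    if len(cells) < 2:
        return out
    pos = {c: i for i, c in enumerate(cells)}
    hit = rng.random(len(out)) < rate
    if hit.any():
        cur = out.loc[hit, "assigned_cell"].map(pos).to_numpy()
        # uniform over the *other* cells
        draw = rng.integers(0, len(cells) - 1, size=int(hit.sum()))
        draw = np.where(draw >= cur, draw + 1, draw)
        out.loc[hit, "assigned_cell"] = np.array(cells, dtype=object)[draw]
    return out


def simulate_experiment(
    config: SimConfig,
    design: CassetteDesign,
    rng: np.random.Generator,
    generate_reads: bool = True,
) -> tuple[SimTruth, list[tuple[str, str, str]]]:
    """Run one synthetic experiment; returns truth tables and FASTQ-ready reads."""
    props = config.lineage_proportions
    lineages = list(props)
    p = np.array([props[l] for l in lineages], dtype=float)

    # founders: one UCI + one recombined cassette each ----------------------
    library = draw_uci_library(config.uci_library_size, config.uci_skew, rng)
    if config.unique_founder_ucis:
        if config.n_founders > config.uci_library_size:
            raise ValueError("unique founder UCIs need n_founders <= library size")
        picks = rng.choice(
            config.uci_library_size,
            size=config.n_founders,
            replace=False,
            p=library["weight"].to_numpy(),
        )
    else:
        picks = rng.choice(
            config.uci_library_size,
            size=config.n_founders,
            replace=True,
            p=library["weight"].to_numpy(),
        )
    founder_ucis = library["uci"].to_numpy()[picks]

    bias = SpanBias(beta=config.bias_beta)
    start = intact_state(design)
    founder_states = [
        simulate_recombination(start, rng, lam=config.recombination_lambda, bias=bias)
        for _ in range(config.n_founders)
    ]
    founder_barcodes = [barcode_string(s.barcode()) for s in founder_states]

    committed = np.array([""] * config.n_founders, dtype=object)
    if config.induction_time == "day8" and config.committed_lineages:
        committed_set = [l for l in lineages if l in config.committed_lineages]
        p_committed = sum(props[l] for l in committed_set)
        is_committed = rng.random(config.n_founders) < p_committed
        if committed_set:
            w = np.array([props[l] for l in committed_set], dtype=float)
            w /= w.sum()
            committed[is_committed] = rng.choice(
                committed_set, size=int(is_committed.sum()), p=w
            )

    founders = pd.DataFrame(
        {
            "founder_id": [f"f{i:05d}" for i in range(config.n_founders)],
            "uci": founder_ucis,
            "polylox": founder_barcodes,
            "committed_lineage": committed,
        }
    )

    # clonal expansion and lineage assignment ------------------------------
    founder_of_cell = np.repeat(
        np.arange(config.n_founders), config.expansion_per_founder
    )
    if config.cells_sampled is not None:
        if config.cells_sampled > founder_of_cell.size:
            raise ValueError("cells_sampled exceeds the expanded pool")
        keep = rng.choice(founder_of_cell.size, config.cells_sampled, replace=False)
        founder_of_cell = founder_of_cell[np.sort(keep)]
    n_cells = founder_of_cell.size

    lineage_of_cell = np.array(
        rng.choice(lineages, size=n_cells, p=p), dtype=object
    )
    if config.induction_time == "day8" and config.committed_lineages:
        somatic = [l for l in lineages if l not in config.committed_lineages]
        ps = np.array([props[l] for l in somatic], dtype=float)
        ps /= ps.sum()
        fc = committed[founder_of_cell]
        from_committed = fc != ""
        lineage_of_cell[from_committed] = fc[from_committed]
        n_som = int((~from_committed).sum())
        lineage_of_cell[~from_committed] = rng.choice(somatic, size=n_som, p=ps)

    barcodes = _cell_barcodes(
        n_cells,
        config.cell_barcode_length,
        rng,
        config.cb_min_pairwise_edits,
        enforce=generate_reads,
    )
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:06d}" for i in range(n_cells)],
            "cell_barcode": barcodes,
            "founder_id": founders["founder_id"].to_numpy()[founder_of_cell],
            "lineage": lineage_of_cell,
        }
    )

    cb_up = _random_seq(rng, config.cb_flank_upstream_length)
    cb_down = _random_seq(rng, config.cb_flank_downstream_length)

    if not generate_reads:
        truth = SimTruth(
            founders,
            cells,
            pd.DataFrame(
                columns=["read_id", "origin_cell", "assigned_cell", "strand", "trunc"]
            ),
            cb_up,
            cb_down,
        )
        return truth, []

    # read plan: counts, contamination, strand ------------------------------
    if config.reads_per_cell_dispersion is None:
        counts = np.full(n_cells, int(round(config.reads_per_cell_mean)))
    else:
        size = config.reads_per_cell_dispersion
        counts = rng.negative_binomial(
            size, size / (size + config.reads_per_cell_mean), size=n_cells
        )
    origin = np.repeat(cells["cell_id"].to_numpy(), counts)
    plan = pd.DataFrame(
        {
            "read_id": [f"read{i:07d}" for i in range(origin.size)],
            "origin_cell": origin,
            "assigned_cell": origin.copy(),
        }
    )
    plan = contaminate(
        plan, config.contamination_rate, rng, cell_ids=list(cells["cell_id"])
    )
    plan["strand"] = np.where(rng.random(len(plan)) < 0.5, "+", "-")

    # render templates, size-select, add noise ------------------------------
    cassette_by_founder = {
        fid: render_sequence(st, design, uci=u)
        for fid, st, u in zip(founders["founder_id"], founder_states, founder_ucis)
    }
    cell_info = cells.set_index("cell_id")
    cb_of = cell_info["cell_barcode"].to_dict()
    founder_of = cell_info["founder_id"].to_dict()

    lo, hi = config.amplicon_size_window
    reads: list[tuple[str, str, str]] = []
    kept_rows = []
    for row in plan.itertuples(index=False):
        cassette = cassette_by_founder[founder_of[row.origin_cell]]
        template = cb_up + cb_of[row.assigned_cell] + cb_down + cassette
        if not lo <= len(template) <= hi:
            continue
        if row.strand == "-":
            template = revcomp(template)
        seq, qual, trunc = mutate_read(
            template,
            config.sub_rate,
            config.ins_rate,
            config.del_rate,
            config.truncation_prob,
            rng,
        )
        reads.append((row.read_id, seq, qual))
        kept_rows.append(
            (row.read_id, row.origin_cell, row.assigned_cell, row.strand, trunc)
        )

    reads_df = pd.DataFrame(
        kept_rows, columns=["read_id", "origin_cell", "assigned_cell", "strand", "trunc"]
    )
    truth = SimTruth(founders, cells, reads_df, cb_up, cb_down)
    return truth, reads
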