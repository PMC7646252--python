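"""Per-cell timestamp-barcode recovery from long reads.

Stages per read: (1) assign a cell barcode by aligning each whitelist entry's
flank-barcode-flank construct (both strands, unit-cost edit distance, unique
best hit); (2) map the spacer blocks and terminal flanks (pBC00,
WPRE_M13R_HSV, M13F) to the re-oriented read and assemble the Polylox string
from hit order and strand; (3) extract the 10-nt UCI between the M13F and
WPRE_M13R_HSV flanks.  Per cell, the most frequent candidate is accepted only
if it clears three filters: detected in more than ``min_reads`` reads, an
upper outlier against the other candidates' counts, and (Polylox) observed
full length / (UCI) matching the plasmid-library whitelist.

All alignment is approximate local matching under unit-cost edits via edlib;
coordinates are 0-based half-open, strands are ``+``/``-``.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .cassette import revcomp

log = logging.getLogger("loxstamp")

_N_EQUALITIES = [("N", b) for b in "ACGT"]


@dataclass(frozen=True)
class CellBarcodeRef:
    """One whitelist entry: 12-nt cell barcode with its 20/24-nt flanks."""

    cell_id: str
    barcode: str
    upstream: str
    downstream: str

    def __post_init__(self) -> None:
        if len(self.barcode) != 12:
            raise ValueError("cell barcode must be 12 nt")
        if len(self.upstream) != 20 or len(self.downstream) != 24:
            raise ValueError("flanks must be 20 nt (upstream) / 24 nt (downstream)")

    @property
    def construct(self) -> str:
        return self.upstream + self.barcode + self.downstream


@dataclass(frozen=True)
class BlockHit:
    """Approximate local match of one reference block on a read."""

    block: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    edit_distance: int

    @property
    def score(self) -> int:
        return -self.edit_distance


@dataclass(frozen=True)
class BarcodeObservation:
    """Per-read detection of cell, Polylox string and UCI."""

    read_id: str
    cell_id: str | None
    polylox: str | None
    full_length: bool
    uci: str | None


@dataclass(frozen=True)
class CallingParams:
    min_reads: int = 30  # strict: candidate count must exceed this
    cb_max_edits: int = 8  # on the 56-nt flank-barcode-flank construct
    block_max_dist_frac: float = 0.25
    flank_max_dist_frac: float = 0.25
    uci_length: int = 10
    uci_length_tol: int = 2
    uci_correct_max_edits: int = 2
    tukey_k: float = 1.5
    dominance_ratio: float = 3.0
    min_candidates_for_tukey: int = 4
    full_length_mode: str = "any"  # candidate seen full length in >=1 read | "majority"


# ---------------------------------------------------------------------------
# cell-barcode assignment


def _best_hit(pattern: str, read: str, k: int = -1, wildcard: bool = False):
    kwargs = {"additionalEqualities": _N_EQUALITIES} if wildcard else {}
    res = edlib.align(pattern, read, mode="HW", task="locations", k=k, **kwargs)
    return res["editDistance"], res["locations"]


def assign_cell_barcode(
    read: str, whitelist: list[CellBarcodeRef], max_edits: int = 8
) -> str | None:
    """Unique best-scoring whitelist cell for a read, or None on tie/miss."""
    if not whitelist:
        raise ValueError("whitelist must be non-empty")
    barcodes = [w.barcode for w in whitelist]
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in whitelist")
    rc = revcomp(read)
    best: tuple[int, str | None] = (max_edits + 1, None)
    tied = False
    for entry in whitelist:
        d = min(
            _best_hit(entry.construct, read, k=max_edits)[0] % (1 << 30),
            _best_hit(entry.construct, rc, k=max_edits)[0] % (1 << 30),
        )
        # edlib returns -1 when above k; the modulus maps it to a huge value
        if d < best[0]:
            best = (d, entry.cell_id)
            tied = False
        elif d == best[0]:
            tied = True
    if tied or best[0] > max_edits:
        return None
    return best[1]


class _CellIndex:
    """Windowed cell-barcode assignment sharing one anchor alignment per read."""

    def __init__(self, whitelist: list[CellBarcodeRef], params: CallingParams):
        if not whitelist:
            raise ValueError("whitelist must be non-empty")
        barcodes = [w.barcode for w in whitelist]
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("duplicate barcodes in whitelist")
        self.whitelist = whitelist
        self.params = params
        w0 = whitelist[0]
        self.anchor = w0.upstream + "N" * len(w0.barcode) + w0.downstream

    def assign(self, oriented_read: str) -> str | None:
        k = self.params.cb_max_edits + len(self.whitelist[0].barcode)
        dist, locs = _best_hit(self.anchor, oriented_read, k=k, wildcard=True)
        if dist == -1 or not locs:
            return None
        start, end = locs[0][0], locs[0][1] + 1
        window = oriented_read[max(0, start - 5) : end + 5]
        best: tuple[int, str | None] = (self.params.cb_max_edits + 1, None)
        tied = False
        for entry in self.whitelist:
            d = edlib.align(
                entry.construct, window, mode="HW", k=self.params.cb_max_edits
            )["editDistance"]
            if d == -1:
                continue
            if d < best[0]:
                best, tied = (d, entry.cell_id), False
            elif d == best[0]:
                tied = True
        if tied or best[0] > self.params.cb_max_edits:
            return None
        return best[1]


# ---------------------------------------------------------------------------
# block mapping and Polylox assembly


def _overlap(a: BlockHit, b: BlockHit) -> bool:
    inter = min(a.end, b.end) - max(a.start, b.start)
    return inter > 0.5 * min(a.end - a.start, b.end - b.start)


def locate_blocks(
    read: str,
    reference: dict[str, str],
    max_dist_frac: float = 0.25,
    both_strands: bool = True,
) -> list[BlockHit]:
    """All approximate block/flank matches on a read, overlap-resolved.

    ``reference`` maps block names (block1..block9, pBC00, M13F,
    WPRE_M13R_HSV) to sequences; a ``loxP`` entry is ignored because the site
    recurs throughout the array.  Hits below the per-block edit-distance
    threshold are kept, overlapping hits resolved to the higher score, and the
    result sorted by read position.
    """
    raw: list[BlockHit] = []
    for name, seq in reference.items():
        if name == "loxP":
            continue
        k = int(max_dist_frac * len(seq))
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            pattern = seq if strand == "+" else revcomp(seq)
            dist, locs = _best_hit(pattern, read, k=k)
            if dist == -1:
                continue
            for start, end in locs:
                hit = BlockHit(name, start, end + 1, strand, dist)
                if not any(h.block == name and _overlap(h, hit) for h in raw):
                    raw.append(hit)
    raw.sort(key=lambda h: (h.edit_distance, h.start, h.block))
    kept: list[BlockHit] = []
    for hit in raw:
        if not any(_overlap(hit, k_) for k_ in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


class ChimericReadError(ValueError):
    """A spacer block occurs more than once in a single read."""


def assemble_polylox(hits: list[BlockHit]) -> tuple[str | None, bool]:
    """Oriented-segment string from position-sorted block hits.

    Raises :class:`ChimericReadError` on duplicate spacer blocks.  Returns
    ``(polylox, full_length)`` where ``full_length`` requires both terminal
    flanks (pBC00 upstream, WPRE_M13R_HSV downstream) around the block run;
    an empty block run between both flanks is the fully excised "EX".
    """
    hits = sorted(hits, key=lambda h: h.start)
    seg_hits = [h for h in hits if h.block.startswith("block")]
    ids = [h.block for h in seg_hits]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ChimericReadError(f"duplicate spacer block(s) {dup}: chimeric read")
    pbc = next((h for h in hits if h.block == "pBC00"), None)
    wpre = next((h for h in hits if h.block == "WPRE_M13R_HSV"), None)
    # read aligned in reverse overall? re-orient using the terminal flanks
    if pbc is not None:
        flipped = pbc.strand == "-"
    elif wpre is not None:
        flipped = wpre.strand == "-"
    else:
        flipped = False
    ordered = list(reversed(seg_hits)) if flipped else seg_hits
    fwd_strand = "-" if flipped else "+"
    segments = [
        (int(h.block[5:]), "+" if h.strand == fwd_strand else "-") for h in ordered
    ]
    full = False
    if pbc is not None and wpre is not None:
        up, down = (wpre, pbc) if flipped else (pbc, wpre)
        full = up.start < down.start and all(
            up.start < h.start and h.end <= down.end for h in seg_hits
        )
    if not seg_hits and not full:
        return None, False
    from .cassette import barcode_string

    polylox = barcode_string(segments)
    return polylox, full


def extract_uci(
    read: str,
    m13f: str,
    wpre: str,
    max_dist_frac: float = 0.25,
    uci_length: int = 10,
    length_tol: int = 2,
) -> str | None:
    """Sequence between the M13F and WPRE_M13R_HSV flanks, or None.

    Both flanks must be found in a consistent orientation and the insert
    length must be within ``uci_length +- length_tol``.
    """
    for seq in (read, revcomp(read)):
        d1, loc1 = _best_hit(m13f, seq, k=int(max_dist_frac * len(m13f)))
        d2, loc2 = _best_hit(wpre, seq, k=int(max_dist_frac * len(wpre)))
        if d1 == -1 or d2 == -1 or not loc1 or not loc2:
            continue
        m_end = loc1[0][1] + 1
        w_start = loc2[0][0]
        if w_start < m_end:
            log.debug("UCI flanks found in inconsistent order; skipping strand")
            continue
        insert = seq[m_end:w_start]
        if abs(len(insert) - uci_length) <= length_tol:
            return insert
    return None


# ---------------------------------------------------------------------------
# per-cell consensus filters


def _outlier_pass(counts: list[int], params: CallingParams) -> bool:
    """Top count must be an upper outlier among the other candidates' counts.

    Tukey upper fence (Q3 + k*IQR) of the remaining counts when there are
    enough candidates; dominance ratio top/second otherwise (second == 0
    passes).
    """
    top, rest = counts[0], counts[1:]
    if len(counts) >= params.min_candidates_for_tukey:
        q1, q3 = np.percentile(rest, [25, 75])
        return top > q3 + params.tukey_k * (q3 - q1)
    second = rest[0] if rest else 0
    return second == 0 or top / second >= params.dominance_ratio


def _top_candidate(counter: Counter) -> tuple[str, int, list[int]]:
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    counts = [c for _, c in ranked]
    return ranked[0][0], ranked[0][1], counts


def call_cell_polylox(
    observations: list[BarcodeObservation], params: CallingParams = CallingParams()
) -> tuple[str | None, dict]:
    """Consensus Polylox for one cell's observations, with filter provenance."""
    counter: Counter = Counter(o.polylox for o in observations if o.polylox)
    flags = {
        "candidate": None,
        "n_top": 0,
        "pass_min_reads": False,
        "pass_outlier": False,
        "pass_full_length": False,
    }
    if not counter:
        return None, flags
    cand, n_top, counts = _top_candidate(counter)
    support = [o for o in observations if o.polylox == cand]
    n_full = sum(o.full_length for o in support)
    flags["candidate"], flags["n_top"] = cand, n_top
    flags["pass_min_reads"] = n_top > params.min_reads
    flags["pass_outlier"] = _outlier_pass(counts, params)
    if params.full_length_mode == "majority":
        flags["pass_full_length"] = n_full * 2 > len(support)
    else:
        flags["pass_full_length"] = n_full >= 1
    ok = all(
        flags[k] for k in ("pass_min_reads", "pass_outlier", "pass_full_length")
    )
    return (cand if ok else None), flags


def correct_uci(
    raw: str, whitelist: list[str], max_edits: int = 2, _cache: dict | None = None
) -> str:
    """Map a raw UCI to its unique whitelist neighbour within ``max_edits``.

    Returns the raw sequence unchanged when there is no neighbour or the
    nearest neighbour is ambiguous.
    """
    if _cache is not None and raw in _cache:
        return _cache[raw]
    out = raw
    if raw not in whitelist:
        best, best_d, tied = None, max_edits + 1, False
        for cand in whitelist:
            d = edlib.align(raw, cand, mode="NW", k=max_edits)["editDistance"]
            if d == -1:
                continue
            if d < best_d:
                best, best_d, tied = cand, d, False
            elif d == best_d:
                tied = True
        if best is not None and not tied:
            out = best
    if _cache is not None:
        _cache[raw] = out
    return out


def call_cell_uci(
    observations: list[BarcodeObservation],
    params: CallingParams = CallingParams(),
    whitelist: set[str] | None = None,
    _correction_cache: dict | None = None,
) -> tuple[str | None, dict]:
    """Consensus UCI for one cell; filter 3 is whitelist membership."""
    ucis = [o.uci for o in observations if o.uci]
    if whitelist is not None:
        wl = sorted(whitelist)
        ucis = [
            u
            if u in whitelist
            else correct_uci(u, wl, params.uci_correct_max_edits, _correction_cache)
            for u in ucis
        ]
    counter: Counter = Counter(ucis)
    flags = {
        "candidate": None,
        "n_top": 0,
        "pass_min_reads": False,
        "pass_outlier": False,
        "pass_whitelist": False,
    }
    if not counter:
        return None, flags
    cand, n_top, counts = _top_candidate(counter)
    flags["candidate"], flags["n_top"] = cand, n_top
    flags["pass_min_reads"] = n_top > params.min_reads
    flags["pass_outlier"] = _outlier_pass(counts, params)
    if whitelist is None:
        warnings.warn("no UCI whitelist provided; whitelist filter skipped")
        flags["pass_whitelist"] = True
    else:
        flags["pass_whitelist"] = cand in whitelist
    ok = all(
        flags[k] for k in ("pass_min_reads", "pass_outlier", "pass_whitelist")
    )
    return (cand if ok else None), flags


# ---------------------------------------------------------------------------
# full pipeline


def _orient_read(read: str, reference: dict[str, str], frac: float) -> str | None:
    """Flip the read so pBC00 lies on the forward strand (None if absent)."""
    pbc = reference["pBC00"]
    k = int(frac * len(pbc))
    d_fwd, _ = _best_hit(pbc, read, k=k)
    d_rev, _ = _best_hit(revcomp(pbc), read, k=k)
    d_fwd = d_fwd % (1 << 30)
    d_rev = d_rev % (1 << 30)
    if min(d_fwd, d_rev) > k:
        return None
    return read if d_fwd <= d_rev else revcomp(read)


def process_read(
    read_id: str,
    seq: str,
    cell_index: _CellIndex,
    reference: dict[str, str],
    params: CallingParams,
) -> BarcodeObservation:
    """Single-read detection of cell barcode, Polylox string and UCI."""
    oriented = _orient_read(seq, reference, params.flank_max_dist_frac)
    if oriented is None:
        return BarcodeObservation(read_id, None, None, False, None)
    cell = cell_index.assign(oriented)
    if cell is None:
        return BarcodeObservation(read_id, None, None, False, None)
    hits = locate_blocks(
        oriented, reference, params.block_max_dist_frac, both_strands=True
    )
    try:
        polylox, full = assemble_polylox(hits)
    except ChimericReadError:
        polylox, full = None, False
    m = next((h for h in hits if h.block == "M13F" and h.strand == "+"), None)
    w = next((h for h in hits if h.block == "WPRE_M13R_HSV" and h.strand == "+"), None)
    uci = None
    if m is not None and w is not None and m.end <= w.start:
        insert = oriented[m.end : w.start]
        if abs(len(insert) - params.uci_length) <= params.uci_length_tol:
            uci = insert
    return BarcodeObservation(read_id, cell, polylox, full, uci)


_CALL_COLUMNS = [
    "cell_id",
    "polylox",
    "uci",
    "timestamp",
    "n_reads_cell",
    "n_reads_polylox_top",
    "n_reads_uci_top",
    "pass_polylox",
    "pass_uci",
    "fail_reasons",
]


def call_timestamps(
    reads: list[tuple[str, str]] | list[tuple[str, str, str]],
    reference: dict[str, str],
    whitelist: list[CellBarcodeRef],
    uci_whitelist: set[str] | None = None,
    params: CallingParams = CallingParams(),
) -> pd.DataFrame:
    """Full calling pipeline: reads -> per-cell timestamp-barcode table.

    A cell receives a timestamp iff both its Polylox and UCI calls pass all
    their filters; failing cells keep their row with the failing filters named
    in ``fail_reasons``.
    """
    index = _CellIndex(whitelist, params)
    by_cell: dict[str, list[BarcodeObservation]] = {}
    n_unassigned = 0
    for rec in reads:
        read_id, seq = rec[0], rec[1]
        obs = process_read(read_id, seq, index, reference, params)
        if obs.cell_id is None:
            n_unassigned += 1
            continue
        by_cell.setdefault(obs.cell_id, []).append(obs)
    if reads:
        log.info(
            "assigned %d/%d reads to cells (%d unassigned)",
            len(reads) - n_unassigned,
            len(reads),
            n_unassigned,
        )
    cache: dict = {}
    rows = []
    for cell_id in sorted(by_cell):
        obs = by_cell[cell_id]
        poly, pflags = call_cell_polylox(obs, params)
        uci, uflags = call_cell_uci(
            obs, params, whitelist=uci_whitelist, _correction_cache=cache
        )
        fails = [
            f"polylox:{k[5:]}" for k in ("pass_min_reads", "pass_outlier", "pass_full_length")
            if not pflags[k]
        ] + [
            f"uci:{k[5:]}" for k in ("pass_min_reads", "pass_outlier", "pass_whitelist")
            if not uflags[k]
        ]
        called = poly is not None and uci is not None
        rows.append(
            {
                "cell_id": cell_id,
                "polylox": poly or "",
                "uci": uci or "",
                "timestamp": f"{poly}:{uci}" if called else "",
                "n_reads_cell": len(obs),
                "n_reads_polylox_top": pflags["n_top"],
                "n_reads_uci_top": uflags["n_top"],
                "pass_polylox": poly is not None,
                "pass_uci": uci is not None,
                "fail_reasons": ";".join(fails),
            }
        )
    return pd.DataFrame(rows, columns=_CALL_COLUMNS)
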