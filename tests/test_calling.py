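"""Read-level detection and per-cell consensus filters."""

import numpy as np
import pandas as pd
import pytest

import loxstamp as lx
from loxstamp.calling import (
    BarcodeObservation,
    BlockHit,
    ChimericReadError,
    _CellIndex,
)
from loxstamp.cassette import CassetteState, LoxSite, SpacerSegment, revcomp


def _whitelist(rng, n=5):
    bases = np.array(list("ACGT"))
    up = "".join(bases[rng.integers(0, 4, 20)])
    down = "".join(bases[rng.integers(0, 4, 24)])
    return [
        lx.CellBarcodeRef(f"c{i}", "".join(bases[rng.integers(0, 4, 12)]), up, down)
        for i in range(n)
    ]


def _edit_distance(a: str, b: str) -> int:
    """Plain DP Levenshtein (independent of edlib)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def _infix_distance(pattern: str, text: str) -> int:
    """Brute-force best edit distance of pattern against any text substring."""
    best = len(pattern)
    for start in range(len(text)):
        for end in range(start, min(len(text), start + 2 * len(pattern)) + 1):
            best = min(best, _edit_distance(pattern, text[start:end]))
    return best


# --------------------------------------------------------------------------
# cell-barcode assignment


def test_assign_exact_match(rng):
    wl = _whitelist(rng)
    read = "AAAA" + wl[2].construct + "TTTT"
    assert lx.assign_cell_barcode(read, wl, max_edits=3) == "c2"


def test_assign_reverse_strand(rng):
    wl = _whitelist(rng)
    read = revcomp("AAAA" + wl[1].construct + "TTTT")
    assert lx.assign_cell_barcode(read, wl, max_edits=3) == "c1"


def test_assign_tie_returns_none(rng):
    wl = _whitelist(rng)
    read = "AA" + wl[0].construct + "CC" + wl[1].construct + "GG"
    assert lx.assign_cell_barcode(read, wl, max_edits=3) is None


def test_assign_one_substitution_vs_bruteforce_oracle(rng):
    wl = _whitelist(rng)
    construct = wl[3].construct
    mutated = construct[:17] + ("A" if construct[17] != "A" else "C") + construct[18:]
    read = "GATTACA" + mutated + "CATGAC"
    # oracle: per-entry brute-force infix distance must be uniquely minimal
    dists = {w.cell_id: _infix_distance(w.construct, read) for w in wl}
    assert dists["c3"] == 1 and sorted(dists.values())[1] > 1
    assert lx.assign_cell_barcode(read, wl, max_edits=3) == "c3"


def test_assign_rejects_duplicate_whitelist(rng):
    wl = _whitelist(rng)
    wl.append(lx.CellBarcodeRef("dup", wl[0].barcode, wl[0].upstream, wl[0].downstream))
    with pytest.raises(ValueError):
        lx.assign_cell_barcode("ACGT" * 30, wl, max_edits=3)


def test_windowed_index_agrees_with_direct_assignment(rng):
    wl = _whitelist(rng, n=20)
    index = _CellIndex(wl, lx.CallingParams())
    for entry in wl[:5]:
        read = "ACGT" * 10 + entry.construct + "TGCA" * 10
        assert index.assign(read) == entry.cell_id
        assert lx.assign_cell_barcode(read, wl, max_edits=8) == entry.cell_id


# --------------------------------------------------------------------------
# block location and assembly


def _state(spec):
    tokens = [LoxSite("+")]
    for sid, orient in spec:
        tokens.append(SpacerSegment(sid, orient))
        tokens.append(LoxSite("-"))
    return CassetteState(tuple(tokens))


def test_locate_blocks_on_clean_read(design):
    refs = design.reference_sequences()
    read = lx.render_sequence(_state([(1, "+"), (4, "-"), (9, "+")]), design, uci="A" * 10)
    hits = lx.locate_blocks(read, refs)
    blocks = [(h.block, h.strand) for h in hits]
    assert blocks == [
        ("pBC00", "+"),
        ("block1", "+"),
        ("block4", "-"),
        ("block9", "+"),
        ("M13F", "+"),
        ("WPRE_M13R_HSV", "+"),
    ]
    assert all(h.edit_distance == 0 for h in hits)


def test_locate_blocks_empty_barcode_flanks_only(design):
    refs = design.reference_sequences()
    read = lx.render_sequence(CassetteState((LoxSite("+"),)), design, uci="A" * 10)
    hits = lx.locate_blocks(read, refs)
    assert [h.block for h in hits] == ["pBC00", "M13F", "WPRE_M13R_HSV"]


def test_locate_blocks_random_sequence_empty(design, rng):
    refs = design.reference_sequences()
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
    assert lx.locate_blocks(seq, refs) == []


def test_assemble_polylox_full_length(design):
    refs = design.reference_sequences()
    read = lx.render_sequence(_state([(1, "+"), (4, "-"), (9, "+")]), design, uci="A" * 10)
    hits = lx.locate_blocks(read, refs)
    assert lx.assemble_polylox(hits) == ("1-4R-9", True)


def test_assemble_polylox_reverse_read(design):
    refs = design.reference_sequences()
    read = revcomp(
        lx.render_sequence(_state([(1, "+"), (4, "-"), (9, "+")]), design, uci="A" * 10)
    )
    hits = lx.locate_blocks(read, refs)
    assert lx.assemble_polylox(hits) == ("1-4R-9", True)


def test_assemble_polylox_missing_terminal_flank():
    hits = [
        BlockHit("block1", 100, 240, "+", 0),
        BlockHit("block4", 300, 440, "-", 0),
        BlockHit("block9", 500, 640, "+", 0),
        BlockHit("WPRE_M13R_HSV", 700, 804, "+", 0),
    ]
    assert lx.assemble_polylox(hits) == ("1-4R-9", False)


def test_assemble_polylox_chimeric_duplicate_block():
    hits = [
        BlockHit("block4", 100, 240, "+", 0),
        BlockHit("block4", 300, 440, "+", 0),
    ]
    with pytest.raises(ChimericReadError):
        lx.assemble_polylox(hits)


def test_assemble_empty_barcode_is_ex():
    hits = [
        BlockHit("pBC00", 0, 550, "+", 0),
        BlockHit("WPRE_M13R_HSV", 700, 804, "+", 0),
    ]
    assert lx.assemble_polylox(hits) == ("EX", True)


# --------------------------------------------------------------------------
# UCI extraction


def test_extract_uci_exact(design):
    f = design.flank_sequences
    read = "TT" + f["M13F"] + "ACGTACGTAC" + f["WPRE_M13R_HSV"] + "GG"
    assert lx.extract_uci(read, f["M13F"], f["WPRE_M13R_HSV"]) == "ACGTACGTAC"
    assert (
        lx.extract_uci(revcomp(read), f["M13F"], f["WPRE_M13R_HSV"]) == "ACGTACGTAC"
    )


def test_extract_uci_missing_flank(design):
    f = design.flank_sequences
    read = "TT" + "ACGTACGTAC" + f["WPRE_M13R_HSV"] + "GG"
    assert lx.extract_uci(read, f["M13F"], f["WPRE_M13R_HSV"]) is None


def test_extract_uci_length_gate(design):
    f = design.flank_sequences
    read = "TT" + f["M13F"] + "ACGTACGTACACGT" + f["WPRE_M13R_HSV"] + "GG"
    assert (
        lx.extract_uci(read, f["M13F"], f["WPRE_M13R_HSV"], length_tol=2) is None
    )


# --------------------------------------------------------------------------
# per-cell consensus filters


def _obs(polylox_counts=(), uci_counts=(), full=True):
    out = []
    i = 0
    for value, count in polylox_counts:
        for _ in range(count):
            out.append(BarcodeObservation(f"r{i}", "c", value, full, None))
            i += 1
    for value, count in uci_counts:
        for _ in range(count):
            out.append(BarcodeObservation(f"r{i}", "c", None, False, value))
            i += 1
    return out


def test_polylox_call_clear_winner():
    obs = _obs(polylox_counts=[("1-4R-9", 40), ("1-9", 2)])
    call, flags = lx.call_cell_polylox(obs)
    assert call == "1-4R-9" and flags["n_top"] == 40


def test_polylox_call_min_reads_is_strict():
    call, flags = lx.call_cell_polylox(_obs(polylox_counts=[("1-2", 25)]))
    assert call is None and not flags["pass_min_reads"]
    call30, flags30 = lx.call_cell_polylox(_obs(polylox_counts=[("1-2", 30)]))
    assert call30 is None and not flags30["pass_min_reads"]
    call31, _ = lx.call_cell_polylox(_obs(polylox_counts=[("1-2", 31)]))
    assert call31 == "1-2"


def test_polylox_call_dominance_fallback_rejects_close_counts():
    obs = _obs(polylox_counts=[("A", 35), ("B", 34)])
    call, flags = lx.call_cell_polylox(obs)
    assert call is None and not flags["pass_outlier"]


def test_polylox_call_requires_full_length_observation():
    obs = _obs(polylox_counts=[("1-2", 40)], full=False)
    call, flags = lx.call_cell_polylox(obs)
    assert call is None and not flags["pass_full_length"]


def test_polylox_tukey_rule_with_many_candidates():
    obs = _obs(
        polylox_counts=[("W", 45), ("a", 2), ("b", 1), ("c", 1), ("d", 2)]
    )
    call, flags = lx.call_cell_polylox(obs)
    assert call == "W" and flags["pass_outlier"]


def test_uci_call_whitelist_filter():
    wl = {"TTGGCCAATT", "ACACACACAC"}
    called, _ = lx.call_cell_uci(_obs(uci_counts=[("TTGGCCAATT", 50)]), whitelist=wl)
    assert called == "TTGGCCAATT"
    missing, flags = lx.call_cell_uci(_obs(uci_counts=[("GGGGGTTTTT", 50)]), whitelist=wl)
    assert missing is None and not flags["pass_whitelist"]


def test_uci_call_boundary_dominant():
    wl = {"TTGGCCAATT"}
    called, _ = lx.call_cell_uci(
        _obs(uci_counts=[("TTGGCCAATT", 31), ("TTGGCCAATA", 1)]), whitelist=wl
    )
    assert called == "TTGGCCAATT"


def test_uci_call_without_whitelist_warns():
    with pytest.warns(UserWarning):
        called, flags = lx.call_cell_uci(_obs(uci_counts=[("TTGGCCAATT", 40)]))
    assert called == "TTGGCCAATT" and flags["pass_whitelist"]


def test_uci_correction_maps_close_reads_to_whitelist():
    wl = ["TTGGCCAATT", "ACACACACAC"]
    assert lx.calling.correct_uci("TTGGCCATT", wl, 2) == "TTGGCCAATT"
    assert lx.calling.correct_uci("GGGGGTTTTT", wl, 2) == "GGGGGTTTTT"


# --------------------------------------------------------------------------
# whole-pipeline properties (zero-noise fixture)


def test_zero_noise_recovery_is_exact(zero_noise_run):
    cfg, truth, reads, wl, uci_wl, calls = zero_noise_run
    merged = (
        calls.merge(truth.cells, on="cell_id")
        .merge(truth.founders, on="founder_id", suffixes=("_call", "_true"))
    )
    assert len(merged) == len(truth.cells)
    assert (merged["timestamp"] != "").all()
    assert (merged["polylox_call"] == merged["polylox_true"]).all()
    assert (merged["uci_call"] == merged["uci_true"]).all()


def test_calls_invariant_to_read_order(zero_noise_run, design, rng):
    cfg, truth, reads, wl, uci_wl, calls = zero_noise_run
    shuffled = list(reads)
    rng.shuffle(shuffled)
    again = lx.call_timestamps(
        shuffled, design.reference_sequences(), wl, uci_wl
    )
    pd.testing.assert_frame_equal(calls, again)


def test_raising_min_reads_never_adds_calls(zero_noise_run, design):
    cfg, truth, reads, wl, uci_wl, _ = zero_noise_run
    refs = design.reference_sequences()
    n_called = []
    for min_reads in (10, 30, 39, 40):
        calls = lx.call_timestamps(
            reads, refs, wl, uci_wl, lx.CallingParams(min_reads=min_reads)
        )
        n_called.append(int((calls["timestamp"] != "").sum()))
    assert n_called == sorted(n_called, reverse=True)
    assert n_called[-1] == 0  # 40 reads/cell cannot exceed a >40 threshold


def test_called_polylox_strings_are_reachable(design3):
    cfg = lx.SimConfig(
        n_founders=6,
        expansion_per_founder=2,
        reads_per_cell_mean=35,
        reads_per_cell_dispersion=None,
        sub_rate=0,
        ins_rate=0,
        del_rate=0,
        truncation_prob=0,
        contamination_rate=0,
        uci_library_size=100,
        amplicon_size_window=(1, 5000),
    )
    truth, reads = lx.simulate_experiment(cfg, design3, np.random.default_rng(21))
    wl = [
        lx.CellBarcodeRef(r.cell_id, r.barcode, r.upstream, r.downstream)
        for r in truth.cell_whitelist().itertuples()
    ]
    calls = lx.call_timestamps(
        reads, design3.reference_sequences(), wl, set(truth.founders["uci"])
    )
    reachable = lx.enumerate_barcodes(design3)
    called = calls.loc[calls["pass_polylox"], "polylox"]
    assert not called.empty
    assert set(called) <= reachable


def test_empty_read_list_gives_empty_table(design, rng):
    wl = _whitelist(rng)
    calls = lx.call_timestamps([], design.reference_sequences(), wl, None)
    assert calls.empty and list(calls.columns)[:4] == [
        "cell_id",
        "polylox",
        "uci",
        "timestamp",
    ]
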