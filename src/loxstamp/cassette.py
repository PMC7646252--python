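"""Tandem-loxP timestamp cassette: recombination substrate, Cre events, barcode space.

The cassette is an array of ``n_segments`` oriented spacer segments interleaved
with ``n_segments + 1`` oriented loxP sites (sites at both ends).  Cre acts on a
pair of sites:

* opposite orientations -> **inversion**: everything strictly between the two
  sites is reversed and orientation-flipped, the boundary sites stay in place;
* same orientation -> **excision**: everything strictly between is deleted
  together with one boundary site, leaving a single site at the junction.

Inversions are reversible, excisions are not, so the reachable "barcode space"
is the closure of the intact state under both event kinds.  A *Polylox barcode*
is the oriented-segment sequence of a state (loxP sites dropped), rendered as
``"1-4R-9"`` style strings; the empty arrangement renders as ``"EX"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

#: canonical 34-nt loxP recognition site
LOXP = "ATAACTTCGTATAATGTATGCTATACGAAGTTAT"

FWD = "+"
REV = "-"
_ORIENTATIONS = (FWD, REV)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def _check_orientation(o: str) -> None:
    if o not in _ORIENTATIONS:
        raise ValueError(f"orientation must be '+' or '-', got {o!r}")


@dataclass(frozen=True)
class LoxSite:
    """A 34-nt loxP site with an orientation on the top strand."""

    orientation: str

    def __post_init__(self) -> None:
        _check_orientation(self.orientation)

    @property
    def sequence(self) -> str:
        return LOXP

    def flipped(self) -> "LoxSite":
        return LoxSite(REV if self.orientation == FWD else FWD)


@dataclass(frozen=True)
class SpacerSegment:
    """An identified spacer block between two loxP sites."""

    id: int
    orientation: str

    def __post_init__(self) -> None:
        if self.id < 1:
            raise ValueError("segment ids are 1-based positive integers")
        _check_orientation(self.orientation)

    def flipped(self) -> "SpacerSegment":
        return SpacerSegment(self.id, REV if self.orientation == FWD else FWD)


Token = LoxSite | SpacerSegment


@dataclass(frozen=True)
class PolyloxBarcode:
    """Oriented-segment arrangement left in the array after recombination."""

    segments: tuple[tuple[int, str], ...]

    @property
    def canonical_string(self) -> str:
        return barcode_string(self)

    @classmethod
    def from_string(cls, text: str) -> "PolyloxBarcode":
        return parse_barcode(text)

    def __len__(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class CassetteState:
    """Alternating loxP-site / spacer-segment token list (sites at both ends)."""

    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        t = self.tokens
        if len(t) % 2 == 0 or not t:
            raise ValueError("token list must have odd length (site at both ends)")
        for i, tok in enumerate(t):
            want = LoxSite if i % 2 == 0 else SpacerSegment
            if not isinstance(tok, want):
                raise ValueError(f"token {i} must be {want.__name__}")
        ids = [tok.id for tok in t[1::2]]
        if len(ids) != len(set(ids)):
            raise ValueError("segment ids must be unique within a cassette")

    @property
    def n_sites(self) -> int:
        return len(self.tokens) // 2 + 1

    @property
    def n_segments(self) -> int:
        return len(self.tokens) // 2

    def site(self, i: int) -> LoxSite:
        return self.tokens[2 * i]  # type: ignore[return-value]

    def segments(self) -> tuple[SpacerSegment, ...]:
        return self.tokens[1::2]  # type: ignore[return-value]

    def barcode(self) -> PolyloxBarcode:
        return PolyloxBarcode(tuple((s.id, s.orientation) for s in self.segments()))


@dataclass(frozen=True)
class CassetteDesign:
    """Static description of a timestamp cassette build.

    ``site_orientations`` defaults to strictly alternating ``+,-,+,-,...`` which
    realises the "converging pairs" layout and is required to reach the full
    barcode space.  Segment and flank sequences are synthetic, generated from
    ``seed`` with a guaranteed pairwise edit distance so block mapping in reads
    is unambiguous.
    """

    n_segments: int = 9
    site_orientations: tuple[str, ...] = ()
    segment_sequences: tuple[str, ...] = ()
    flank_sequences: dict = field(default_factory=dict)
    uci_length: int = 10
    seed: int = 20200

    def __post_init__(self) -> None:
        if self.n_segments < 0:
            raise ValueError("n_segments must be non-negative")
        if not self.site_orientations:
            object.__setattr__(
                self,
                "site_orientations",
                tuple(FWD if i % 2 == 0 else REV for i in range(self.n_segments + 1)),
            )
        if len(self.site_orientations) != self.n_segments + 1:
            raise ValueError(
                "site_orientations must have length n_segments + 1 "
                f"({self.n_segments + 1}), got {len(self.site_orientations)}"
            )
        for o in self.site_orientations:
            _check_orientation(o)

    # -- sequence material -------------------------------------------------

    @classmethod
    def generate(
        cls,
        n_segments: int = 9,
        segment_length: int = 140,
        pbc00_length: int = 550,
        m13f_length: int = 74,
        wpre_length: int = 104,
        site_orientations: Sequence[str] = (),
        seed: int = 20200,
        min_pairwise_edits: int = 10,
    ) -> "CassetteDesign":
        """Generate a design with synthetic, mutually distinguishable sequences."""
        import edlib

        rng = np.random.default_rng(seed)
        lengths = [segment_length] * n_segments + [pbc00_length, m13f_length, wpre_length]
        seqs: list[str] = []
        bases = np.array(list("ACGT"))
        while len(seqs) < len(lengths):
            cand = "".join(rng.choice(bases, size=lengths[len(seqs)]))
            ok = True
            for prev in seqs + [LOXP]:
                k = min_pairwise_edits - 1
                if edlib.align(cand, prev, mode="NW", k=k)["editDistance"] != -1:
                    ok = False
                    break
            if ok:
                seqs.append(cand)
        segs = tuple(seqs[:n_segments])
        flanks = {
            "pBC00": seqs[n_segments],
            "M13F": seqs[n_segments + 1],
            "WPRE_M13R_HSV": seqs[n_segments + 2],
        }
        return cls(
            n_segments=n_segments,
            site_orientations=tuple(site_orientations),
            segment_sequences=segs,
            flank_sequences=flanks,
            seed=seed,
        )

    def segment_sequence(self, segment_id: int) -> str:
        if not self.segment_sequences:
            raise ValueError("design carries no segment sequences")
        if not 1 <= segment_id <= len(self.segment_sequences):
            raise KeyError(f"no sequence for segment id {segment_id}")
        return self.segment_sequences[segment_id - 1]

    def reference_sequences(self) -> dict[str, str]:
        """Block/flank reference used for read mapping (FASTA-ready)."""
        ref = {f"block{i + 1}": s for i, s in enumerate(self.segment_sequences)}
        ref.update(self.flank_sequences)
        ref["loxP"] = LOXP
        return ref

    def to_dict(self) -> dict:
        return {
            "n_segments": self.n_segments,
            "site_orientations": list(self.site_orientations),
            "segment_sequences": list(self.segment_sequences),
            "flank_sequences": dict(self.flank_sequences),
            "uci_length": self.uci_length,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CassetteDesign":
        return cls(
            n_segments=d["n_segments"],
            site_orientations=tuple(d.get("site_orientations") or ()),
            segment_sequences=tuple(d.get("segment_sequences") or ()),
            flank_sequences=dict(d.get("flank_sequences") or {}),
            uci_length=d.get("uci_length", 10),
            seed=d.get("seed", 20200),
        )


def intact_state(design: CassetteDesign) -> CassetteState:
    """Unrecombined cassette: all segments forward in id order."""
    tokens: list[Token] = []
    for i in range(design.n_segments):
        tokens.append(LoxSite(design.site_orientations[i]))
        tokens.append(SpacerSegment(i + 1, FWD))
    tokens.append(LoxSite(design.site_orientations[design.n_segments]))
    return CassetteState(tuple(tokens))


class NotRecombinableError(ValueError):
    """Raised when a site pair cannot support the requested event."""


def _check_pair(state: CassetteState, i: int, j: int) -> None:
    if not 0 <= i < j < state.n_sites:
        raise IndexError(f"need 0 <= i < j < {state.n_sites}, got ({i}, {j})")


def apply_inversion(state: CassetteState, i: int, j: int) -> CassetteState:
    """Invert between sites ``i`` and ``j`` (opposite orientations required)."""
    _check_pair(state, i, j)
    if state.site(i).orientation == state.site(j).orientation:
        raise NotRecombinableError(
            f"sites {i} and {j} have the same orientation: not invertible"
        )
    t = state.tokens
    mid = tuple(tok.flipped() for tok in reversed(t[2 * i + 1 : 2 * j]))
    return CassetteState(t[: 2 * i + 1] + mid + t[2 * j :])


def apply_excision(state: CassetteState, i: int, j: int) -> CassetteState:
    """Excise between sites ``i`` and ``j`` (same orientation required)."""
    _check_pair(state, i, j)
    if state.site(i).orientation != state.site(j).orientation:
        raise NotRecombinableError(
            f"sites {i} and {j} have opposite orientations: not excisable"
        )
    t = state.tokens
    return CassetteState(t[: 2 * i + 1] + t[2 * j + 1 :])


EXCISION = "excision"
INVERSION = "inversion"


def legal_events(state: CassetteState) -> list[tuple[int, int, str]]:
    """All legal (i, j, kind) Cre events of the current state."""
    out = []
    orients = [state.site(i).orientation for i in range(state.n_sites)]
    for i in range(state.n_sites):
        for j in range(i + 1, state.n_sites):
            kind = EXCISION if orients[i] == orients[j] else INVERSION
            out.append((i, j, kind))
    return out


def apply_event(state: CassetteState, event: tuple[int, int, str]) -> CassetteState:
    i, j, kind = event
    if kind == EXCISION:
        return apply_excision(state, i, j)
    if kind == INVERSION:
        return apply_inversion(state, i, j)
    raise ValueError(f"unknown event kind {kind!r}")


@dataclass(frozen=True)
class SpanBias:
    """Default event-weight model: shorter-range events dominate.

    weight(i, j, kind) = kind_multiplier * exp(-beta * (j - i)), qualitatively
    reproducing the strong bias toward a limited set of products without
    claiming measured kinetics.
    """

    beta: float = 1.0
    excision_weight: float = 1.0
    inversion_weight: float = 1.0

    def __call__(self, state: CassetteState, event: tuple[int, int, str]) -> float:
        i, j, kind = event
        mult = self.excision_weight if kind == EXCISION else self.inversion_weight
        return mult * float(np.exp(-self.beta * (j - i)))


def simulate_recombination(
    state: CassetteState,
    rng: np.random.Generator,
    lam: float = 2.0,
    bias: Callable[[CassetteState, tuple[int, int, str]], float] | None = None,
    n_events: int | None = None,
) -> CassetteState:
    """Apply a Poisson(lam) number of bias-weighted sequential Cre events."""
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if bias is None:
        bias = SpanBias()
    if n_events is None:
        n_events = int(rng.poisson(lam))
    for _ in range(n_events):
        events = legal_events(state)
        if not events:
            break
        weights = np.array([bias(state, e) for e in events], dtype=float)
        if np.any(weights < 0):
            raise ValueError("bias weights must be non-negative")
        total = weights.sum()
        if total <= 0:
            warnings.warn("all-zero bias over legal events; stopping early")
            break
        idx = rng.choice(len(events), p=weights / total)
        state = apply_event(state, events[idx])
    return state


# ---------------------------------------------------------------------------
# canonical barcode rendering


def barcode_string(barcode: PolyloxBarcode | Sequence[tuple[int, str]]) -> str:
    """Render ``[(1,'+'),(4,'-'),(9,'+')]`` as ``"1-4R-9"``; empty as ``"EX"``."""
    segs = barcode.segments if isinstance(barcode, PolyloxBarcode) else tuple(barcode)
    if not segs:
        return "EX"
    parts = []
    for sid, orient in segs:
        _check_orientation(orient)
        parts.append(f"{sid}R" if orient == REV else str(sid))
    return "-".join(parts)


def parse_barcode(text: str) -> PolyloxBarcode:
    """Inverse of :func:`barcode_string`."""
    if text == "EX":
        return PolyloxBarcode(())
    segs = []
    for token in text.split("-"):
        body, orient = (token[:-1], REV) if token.endswith("R") else (token, FWD)
        if not body.isdigit() or int(body) < 1:
            raise ValueError(f"malformed barcode token {token!r} in {text!r}")
        segs.append((int(body), orient))
    return PolyloxBarcode(tuple(segs))


# ---------------------------------------------------------------------------
# sequence rendering


def render_sequence(
    state: CassetteState, design: CassetteDesign, uci: str | None = None
) -> str:
    """5'->3' amplicon sequence: pBC00, array tokens, M13F, UCI, WPRE_M13R_HSV.

    Reverse-oriented tokens are reverse-complemented.  ``uci=None`` renders an
    ``N``-placeholder of the designed UCI length.
    """
    for name in ("pBC00", "M13F", "WPRE_M13R_HSV"):
        if name not in design.flank_sequences:
            raise KeyError(f"design is missing flank sequence {name!r}")
    parts = [design.flank_sequences["pBC00"]]
    for tok in state.tokens:
        if isinstance(tok, LoxSite):
            seq = LOXP
        else:
            seq = design.segment_sequence(tok.id)
        parts.append(seq if tok.orientation == FWD else revcomp(seq))
    parts.append(design.flank_sequences["M13F"])
    parts.append(uci if uci is not None else "N" * design.uci_length)
    parts.append(design.flank_sequences["WPRE_M13R_HSV"])
    return "".join(parts)


# ---------------------------------------------------------------------------
# barcode-space enumeration
#
# Breadth-first closure over full states.  States are encoded as int8 rows
# (site tokens at even columns as +-10, segments at odd columns as +-id) and
# levels (= segment counts) are processed top-down: inversions stay within a
# level, excisions feed lower levels.  Whole frontiers are expanded with numpy
# column arithmetic, and visited sets are kept as int64 keys
#     key = (sum_i segcode_i * 18^i) * 2^(k+1) + site_orientation_bits
# which fits the 9-segment design comfortably in 64 bits.

_SITE = 10  # int8 magnitude marking a site token


def _intact_row(design: CassetteDesign) -> np.ndarray:
    row = np.zeros(2 * design.n_segments + 1, dtype=np.int8)
    for i, o in enumerate(design.site_orientations):
        row[2 * i] = _SITE if o == FWD else -_SITE
    for s in range(design.n_segments):
        row[2 * s + 1] = s + 1
    return row


def _encode_states(arr: np.ndarray) -> np.ndarray:
    """int8 state rows -> int64 keys (level-specific layout)."""
    segs = arr[:, 1::2].astype(np.int64)
    key = np.zeros(arr.shape[0], dtype=np.int64)
    for i in range(segs.shape[1]):
        key = key * 18 + (np.abs(segs[:, i]) - 1) * 2 + (segs[:, i] < 0)
    sites = arr[:, ::2] < 0
    for i in range(sites.shape[1]):
        key = key * 2 + sites[:, i]
    return key


def _barcode_keys_from_state_keys(keys: np.ndarray, k: int) -> np.ndarray:
    """Project state keys to barcode keys (drop site bits, tag the length)."""
    seg_part = keys >> np.int64(k + 1)
    return seg_part * 16 + k


def _decode_barcode_key(key: int) -> str:
    k = key % 16
    seg_part = key // 16
    codes = []
    for _ in range(k):
        seg_part, code = divmod(seg_part, 18)
        codes.append(code)
    codes.reverse()
    return barcode_string([(c // 2 + 1, REV if c % 2 else FWD) for c in codes])


def _new_rows(cand: np.ndarray, seen_keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deduplicate candidate rows and drop those already in ``seen_keys``."""
    keys = _encode_states(cand)
    keys, order = np.unique(keys, return_index=True)
    cand = cand[order]
    if seen_keys.size:
        fresh = ~np.isin(keys, seen_keys, assume_unique=True)
        keys, cand = keys[fresh], cand[fresh]
    return cand, keys


def _closure_barcode_keys(design: CassetteDesign, chunk: int = 250_000) -> np.ndarray:
    """All reachable barcodes (as int64 keys) for a design with <= 9 segments."""
    if design.n_segments > 9:
        raise ValueError("enumeration is guarded to n_segments <= 9")
    n = design.n_segments
    pending: dict[int, list[np.ndarray]] = {k: [] for k in range(n + 1)}
    pending[n].append(_intact_row(design)[None, :])
    barcode_parts: list[np.ndarray] = []

    for k in range(n, -1, -1):
        if not pending[k]:
            continue
        visited = np.empty(0, dtype=np.int64)
        frontier, fkeys = _new_rows(np.concatenate(pending[k]), visited)
        pending[k] = []
        while frontier.size:
            visited = np.union1d(visited, fkeys)
            next_parts: list[np.ndarray] = []
            for lo in range(0, frontier.shape[0], chunk):
                block = frontier[lo : lo + chunk]
                for a in range(k + 1):
                    for b in range(a + 1, k + 1):
                        ca, cb = block[:, 2 * a], block[:, 2 * b]
                        opp = (ca > 0) != (cb > 0)
                        if opp.any():
                            inv = block[opp].copy()
                            inv[:, 2 * a + 1 : 2 * b] = -inv[:, 2 * b - 1 : 2 * a : -1]
                            next_parts.append(inv)
                        same = ~opp
                        if same.any():
                            exc = np.concatenate(
                                (block[same, : 2 * a + 1], block[same, 2 * b + 1 :]),
                                axis=1,
                            )
                            pending[k - (b - a)].append(exc)
            if next_parts:
                frontier, fkeys = _new_rows(np.concatenate(next_parts), visited)
            else:
                frontier = np.empty((0, 2 * k + 1), dtype=np.int8)
                fkeys = np.empty(0, dtype=np.int64)
        barcode_parts.append(np.unique(_barcode_keys_from_state_keys(visited, k)))
    return np.unique(np.concatenate(barcode_parts))


def barcode_space_size(design: CassetteDesign) -> int:
    """Number of distinct reachable oriented-segment arrangements."""
    return int(_closure_barcode_keys(design).size)


def enumerate_barcodes(design: CassetteDesign) -> set[str]:
    """Breadth-first closure from the intact state over all legal Cre events.

    Returns every distinct oriented-segment arrangement (canonical strings),
    including the intact barcode and, when reachable, the fully excised "EX".
    """
    keys = _closure_barcode_keys(design)
    return {_decode_barcode_key(int(key)) for key in keys}
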