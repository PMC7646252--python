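"""Clonal frequency estimation and the low-complexity timestamp filter.

Recombination bias and the skewed UCI library over-represent some timestamp
barcodes, which would connect unrelated clones in the linkage map.  Because
the Polylox arrangement and the UCI draw are independent events, the frequency
of a timestamp barcode is estimated as the product of its component
frequencies, and cells whose estimated frequency exceeds a cutoff (strictly)
are excluded.  Frequencies are computed per embryoid body when an EB mapping
is given, pooled otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: cutoffs used for the published sensitivity sweep
SWEEP_CUTOFFS = (1 / 1000, 3 / 1000, 5 / 1000, 1 / 100)

_POOLED = "pooled"


def _called(calls: pd.DataFrame) -> pd.DataFrame:
    return calls[calls["pass_polylox"] & calls["pass_uci"]]


def _with_scope(calls: pd.DataFrame, eb: pd.Series | None) -> pd.DataFrame:
    out = calls.copy()
    if eb is None:
        out["scope"] = _POOLED
    else:
        out["scope"] = out["cell_id"].map(eb)
        if out["scope"].isna().any():
            missing = out.loc[out["scope"].isna(), "cell_id"].tolist()[:5]
            raise ValueError(f"cells without an EB assignment, e.g. {missing}")
    return out


def component_frequencies(
    calls: pd.DataFrame, eb: pd.Series | None = None, mode: str = "cells"
) -> pd.DataFrame:
    """Relative frequency of each called UCI and Polylox within each scope.

    ``mode='cells'`` counts called cells (default); ``mode='reads'`` weights
    each cell by its supporting read count, approximating a per-read
    frequency.  Returns a long table (scope, component, barcode, frequency).
    """
    if calls.empty:
        raise ValueError("calls table is empty")
    called = _with_scope(_called(calls), eb)
    if called.empty:
        raise ValueError("no cell passed both component filters")
    rows = []
    for (scope,), group in called.groupby(["scope"]):
        if group.empty:  # pragma: no cover - groupby drops empty groups
            warnings.warn(f"scope {scope} has zero calls; omitted")
            continue
        for component, col, n_col in (
            ("uci", "uci", "n_reads_uci_top"),
            ("polylox", "polylox", "n_reads_polylox_top"),
        ):
            if mode == "reads":
                counts = group.groupby(col)[n_col].sum()
            else:
                counts = group.groupby(col).size()
            freq = counts / counts.sum()
            for barcode, f in freq.items():
                rows.append((scope, component, barcode, float(f)))
    return pd.DataFrame(rows, columns=["scope", "component", "barcode", "frequency"])


def timestamp_frequency(
    component_freq: pd.DataFrame, pairs: pd.DataFrame
) -> pd.DataFrame:
    """Independence estimate freq(timestamp) = freq(uci) * freq(polylox).

    ``pairs`` holds the observed (polylox, uci) combinations (a ``scope``
    column is optional; missing means pooled).  One output row per distinct
    (scope, polylox, uci), with the product estimate and, for diagnostics,
    the empirical pair frequency among the rows of ``pairs``.
    """
    pairs = pairs.copy()
    if "scope" not in pairs.columns:
        pairs["scope"] = _POOLED
    lut = {
        (r.scope, r.component, r.barcode): r.frequency
        for r in component_freq.itertuples()
    }
    scope_sizes = pairs.groupby("scope").size()
    rows = []
    for (scope, poly, uci), group in pairs.groupby(["scope", "polylox", "uci"]):
        try:
            f_u = lut[(scope, "uci", uci)]
            f_p = lut[(scope, "polylox", poly)]
        except KeyError as exc:
            raise ValueError(f"pair references unseen component: {exc}") from exc
        rows.append((scope, poly, uci, f_u * f_p, len(group) / scope_sizes[scope]))
    return pd.DataFrame(
        rows, columns=["scope", "polylox", "uci", "frequency", "empirical_frequency"]
    )


def filter_high_frequency(
    calls: pd.DataFrame,
    cutoff: float = 0.005,
    eb: pd.Series | None = None,
    mode: str = "cells",
    sweep: tuple[float, ...] = SWEEP_CUTOFFS,
    timestamp_freq: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop cells whose estimated timestamp frequency strictly exceeds ``cutoff``.

    Returns (retained calls, report).  The report gives retained counts and
    fractions at every sweep cutoff (the requested cutoff included).  Pass a
    precomputed ``timestamp_freq`` table to filter against fixed frequencies
    (e.g. for sensitivity sweeps over one estimate).
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError("cutoff must be in (0, 1]")
    called = _with_scope(_called(calls), eb)
    if timestamp_freq is None:
        comp = component_frequencies(calls, eb=eb, mode=mode)
        timestamp_freq = timestamp_frequency(comp, called)
    lut = {(r.scope, r.polylox, r.uci): r.frequency for r in timestamp_freq.itertuples()}
    freq = np.array(
        [lut[(r.scope, r.polylox, r.uci)] for r in called.itertuples()], dtype=float
    )
    n_called = len(called)
    report_rows = []
    for c in sorted(set(sweep) | {cutoff}):
        kept = int((freq <= c).sum())
        report_rows.append((c, kept, kept / n_called if n_called else np.nan))
    report = pd.DataFrame(
        report_rows, columns=["cutoff", "retained_cells", "retained_fraction"]
    )
    retained_ids = set(called.loc[freq <= cutoff, "cell_id"])
    retained = calls[calls["cell_id"].isin(retained_ids)].copy()
    return retained, report
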