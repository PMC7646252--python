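"""Lineage linkage map and coupling statistics from shared timestamp barcodes.

Cells carrying an identical timestamp barcode (Polylox arrangement + UCI)
descend from one founder clone; connecting them and colouring by
transcriptome-derived lineage labels yields the linkage map.  Coupling between
lineages is quantified two ways: Spearman rank correlation of per-lineage
counts over shared barcodes, and an observed-to-expected enrichment of
cross-lineage linkage edges against a label-permutation null (barcode
assignments fixed, lineage labels shuffled across cells).
"""

from __future__ import annotations

import warnings
from itertools import combinations, combinations_with_replacement

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def join_lineages(calls: pd.DataFrame, lineages: pd.DataFrame) -> pd.DataFrame:
    """Inner-join filtered calls with per-cell lineage labels.

    Low-confidence labels are excluded; cells without a confident label are
    dropped (their count is reported via a warning-level log only when any).
    ``lineages`` needs columns cell_id and lineage, plus optional
    ``confidence`` (boolean or "high"/"low").
    """
    for df, name in ((calls, "calls"), (lineages, "lineages")):
        if df["cell_id"].duplicated().any():
            raise ValueError(f"duplicate cell ids in {name} table")
    lin = lineages.copy()
    if "confidence" in lin.columns:
        conf = lin["confidence"]
        ok = conf.map(
            lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).lower()
            not in ("low", "false", "0")
        )
        lin = lin[ok]
    called = calls[calls["timestamp"] != ""] if "timestamp" in calls.columns else calls
    merged = called.merge(lin[["cell_id", "lineage"]], on="cell_id", how="inner")
    n_dropped = len(called) - len(merged)
    if n_dropped:
        warnings.warn(f"{n_dropped} called cells had no confident lineage label")
    return merged


def build_linkage_edges(annotated: pd.DataFrame) -> pd.DataFrame:
    """One edge per unordered cell pair sharing an identical timestamp barcode."""
    rows = []
    for barcode, group in annotated.groupby("timestamp", sort=True):
        cells = group[["cell_id", "lineage"]].sort_values("cell_id").to_numpy()
        for (ca, la), (cb, lb) in combinations(cells.tolist(), 2):
            rows.append((ca, cb, barcode, la, lb))
    return pd.DataFrame(
        rows, columns=["cell_a", "cell_b", "barcode", "lineage_a", "lineage_b"]
    )


def lineage_barcode_matrix(annotated: pd.DataFrame) -> pd.DataFrame:
    """Lineage x shared-barcode cell-count table (shared = seen in >= 2 cells)."""
    counts = annotated.groupby("timestamp")["cell_id"].nunique()
    shared = counts.index[counts >= 2]
    if shared.empty:
        warnings.warn("no shared timestamp barcodes")
        return pd.DataFrame(index=sorted(annotated["lineage"].unique()))
    sub = annotated[annotated["timestamp"].isin(shared)]
    mat = pd.crosstab(sub["lineage"], sub["timestamp"])
    return mat.reindex(sorted(annotated["lineage"].unique()), fill_value=0)


def lineage_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlation of lineage count vectors over shared barcodes.

    Symmetric with unit diagonal; undefined correlations (constant vectors)
    are reported as missing (NaN).
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 shared barcodes for correlation")
    lineages = list(matrix.index)
    out = pd.DataFrame(np.eye(len(lineages)), index=lineages, columns=lineages)
    for a, b in combinations(lineages, 2):
        va, vb = matrix.loc[a].to_numpy(), matrix.loc[b].to_numpy()
        if np.all(va == va[0]) or np.all(vb == vb[0]):
            rho = np.nan
        else:
            rho = stats.spearmanr(va, vb).statistic
        out.loc[a, b] = out.loc[b, a] = rho
    return out


def sharing_enrichment(
    annotated: pd.DataFrame,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed-to-expected linkage-edge counts per lineage pair.

    Expected counts come from permuting lineage labels across cells with the
    barcode assignments fixed.  Per unordered lineage pair (including
    within-lineage pairs) the table reports observed, expected (permutation
    mean), obs/exp ratio, a two-sided permutation p-value with add-one
    correction (deviation from the permutation mean) and Benjamini-Hochberg
    q-values across pairs.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if annotated.empty:
        raise ValueError("no annotated cells to analyse")
    if rng is None:
        rng = np.random.default_rng()
    lineages = sorted(annotated["lineage"].unique())
    code = {l: i for i, l in enumerate(lineages)}
    L = len(lineages)
    labels = annotated["lineage"].map(code).to_numpy(dtype=np.int64)

    # edge endpoints as positional indices into `annotated`
    pos = pd.Series(np.arange(len(annotated)), index=annotated["cell_id"].to_numpy())
    ia_parts, ib_parts = [], []
    for _, group in annotated.groupby("timestamp", sort=True):
        idx = pos[group["cell_id"].sort_values()].to_numpy()
        if idx.size < 2:
            continue
        a, b = np.triu_indices(idx.size, k=1)
        ia_parts.append(idx[a])
        ib_parts.append(idx[b])
    if ia_parts:
        ia = np.concatenate(ia_parts)
        ib = np.concatenate(ib_parts)
    else:
        ia = ib = np.empty(0, dtype=int)

    def pair_counts(lab: np.ndarray) -> np.ndarray:
        la, lb = lab[ia], lab[ib]
        lo, hi = np.minimum(la, lb), np.maximum(la, lb)
        return np.bincount(lo * L + hi, minlength=L * L)

    obs = pair_counts(labels)
    perm = np.empty((n_perm, L * L), dtype=np.int64)
    for p in range(n_perm):
        perm[p] = pair_counts(rng.permutation(labels))
    expected = perm.mean(axis=0)
    dev = np.abs(perm - expected)
    obs_dev = np.abs(obs - expected)
    p_emp = (1 + (dev >= obs_dev).sum(axis=0)) / (n_perm + 1)

    rows = []
    for i, j in combinations_with_replacement(range(L), 2):
        k = i * L + j
        exp = expected[k]
        rows.append(
            {
                "lineage_a": lineages[i],
                "lineage_b": lineages[j],
                "observed": int(obs[k]),
                "expected": float(exp),
                "ratio": float(obs[k] / exp) if exp > 0 else np.nan,
                "p": float(p_emp[k]),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
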