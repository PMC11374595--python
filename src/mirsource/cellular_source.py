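"""Cellular sourcing of miRNAs by the pseudocounted diagnostic odds ratio.

A feature is "detected" in a cell when its (normalized) expression value
exceeds zero. For each candidate cell group, a one-vs-rest contingency
table is formed — TP: in-group cells with detection, FP: out-group cells
with detection, FN: in-group without, TN: out-group without — and the
diagnostic odds ratio is computed with a 0.5 pseudocount in every cell of
the table so it is always finite and positive:

    DOR = ((TP + 0.5) / (FP + 0.5)) / ((FN + 0.5) / (TN + 0.5))

A feature detected in fewer than 5% of the cells of a group is considered
non-significant there (the minimum-detection filter); the filter is
applied at reporting so every DOR remains inspectable. The cellular
source of a miRNA is the group where its DOR is maximal among groups
passing the filter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .sc_core import merge_subtype_groups

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("contingency counts must be non-negative")


def dor_from_table(tp, fp, fn, tn, pseudocount: float = 0.5):
    """Pseudocounted diagnostic odds ratio from contingency counts.

    Accepts scalars or numpy arrays. With the default 0.5 pseudocount the
    result is finite and strictly positive for any non-negative counts;
    ``pseudocount=0`` gives the classical DOR (may divide by zero).
    """
    tp = np.asarray(tp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    fn = np.asarray(fn, dtype=float)
    tn = np.asarray(tn, dtype=float)
    c = pseudocount
    out = ((tp + c) / (fp + c)) / ((fn + c) / (tn + c))
    return out if out.ndim else float(out)


@dataclass
class DORResult:
    feature: str
    group: str
    contingency: ContingencyTable
    detection_in: float
    detection_out: float
    dor: float
    passes_min_detection: bool


def binarize(adata: ad.AnnData, feature: str) -> np.ndarray:
    """Boolean detection vector for one feature: normalized value > 0
    (identical to counts > 0 because CP10K/log1p preserve zeros)."""
    if feature not in adata.var_names:
        raise KeyError(f"unknown feature {feature!r}")
    j = adata.var_names.get_loc(feature)
    layer = adata.layers["normalized"] if "normalized" in adata.layers else adata.X
    col = layer[:, j]
    if sp.issparse(col):
        col = col.toarray()
    return np.asarray(col).ravel() > 0


def dor(
    adata: ad.AnnData,
    feature: str,
    groups: dict[str, np.ndarray] | str = "cell_subtype",
    min_detection: float = 0.05,
) -> list[DORResult]:
    """One-vs-rest DOR of a feature across cell groups.

    ``groups`` may be a grouping level name (merged via
    :func:`merge_subtype_groups`) or an explicit group -> cell-index map
    with at least two groups. Results are returned for every group; the
    minimum-detection flag (`detection_in >= min_detection`) is recorded
    but not used to drop rows here — filtering happens at reporting.
    """
    if isinstance(groups, str):
        groups = merge_subtype_groups(adata, groups)
    if len(groups) < 2:
        raise ValueError("need at least two cell groups")
    det = binarize(adata, feature)
    n_cells = adata.n_obs
    n_det_total = int(det.sum())
    results = []
    for name in sorted(groups):
        idx = np.asarray(groups[name])
        if idx.size == 0:
            logger.warning("group %s has no cells; skipped", name)
            continue
        tp = int(det[idx].sum())
        fn = idx.size - tp
        fp = n_det_total - tp
        tn = (n_cells - idx.size) - fp
        table = ContingencyTable(tp, fp, fn, tn)
        d_in = tp / idx.size
        d_out = fp / (n_cells - idx.size) if n_cells > idx.size else 0.0
        results.append(
            DORResult(
                feature=feature,
                group=name,
                contingency=table,
                detection_in=d_in,
                detection_out=d_out,
                dor=dor_from_table(tp, fp, fn, tn),
                passes_min_detection=d_in >= min_detection,
            )
        )
    return results


def dor_table(
    adata: ad.AnnData,
    features: list[str],
    groups: dict[str, np.ndarray] | str = "cell_subtype",
    min_detection: float = 0.05,
) -> pd.DataFrame:
    """DOR results for many features as one tidy DataFrame."""
    if isinstance(groups, str):
        groups = merge_subtype_groups(adata, groups)
    rows = []
    for feature in features:
        for r in dor(adata, feature, groups, min_detection):
            rows.append(
                (r.feature, r.group, r.contingency.TP, r.contingency.FP,
                 r.contingency.FN, r.contingency.TN, r.detection_in,
                 r.detection_out, r.dor, r.passes_min_detection)
            )
    return pd.DataFrame(
        rows,
        columns=["feature", "group", "TP", "FP", "FN", "TN",
                 "detection_in", "detection_out", "dor", "passes_min_detection"],
    )


def rank_sources(results: list[DORResult] | pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k candidate source groups per feature by descending DOR.

    Only groups passing the minimum-detection filter are ranked; a feature
    below the threshold everywhere yields no rows. Reports DOR and
    in-group detection fraction (dot size in the usual presentation).
    """
    if isinstance(results, list):
        df = pd.DataFrame(
            [
                (r.feature, r.group, r.dor, r.detection_in, r.passes_min_detection)
                for r in results
            ],
            columns=["feature", "group", "dor", "detection_in", "passes_min_detection"],
        )
    else:
        df = results[["feature", "group", "dor", "detection_in", "passes_min_detection"]].copy()
    df = df[df["passes_min_detection"]]
    df = df.sort_values(
        ["feature", "dor", "group"], ascending=[True, False, True], kind="mergesort"
    )
    df["rank"] = df.groupby("feature").cumcount() + 1
    return df[df["rank"] <= k].reset_index(drop=True)


def state_expression_compare(
    adata: ad.AnnData,
    feature: str,
    source_group: str,
    level: str = "cell_subtype",
    min_cells: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disease-state comparison of a miRNA within its source group.

    Returns ``(summary, tests)``: per-state mean normalized expression and
    detection fraction, and pairwise two-sided Wilcoxon rank-sum tests
    between states with BH adjustment. States with fewer than ``min_cells``
    cells are summarized but excluded from testing (noted in the summary).
    """
    if "disease_state" not in adata.obs:
        raise ValueError("disease_state labels required")
    if "normalized" not in adata.layers:
        raise ValueError("normalized layer required; run normalize() first")
    groups = merge_subtype_groups(adata, level)
    if source_group not in groups:
        raise ValueError(f"unknown source group {source_group!r}")
    idx = groups[source_group]
    j = adata.var_names.get_loc(feature)
    vals = adata.layers["normalized"][idx, j]
    if sp.issparse(vals):
        vals = vals.toarray()
    vals = np.asarray(vals).ravel()
    states = adata.obs["disease_state"].to_numpy()[idx]

    summary_rows = []
    by_state: dict[str, np.ndarray] = {}
    for state in sorted(set(states)):
        v = vals[states == state]
        by_state[state] = v
        summary_rows.append(
            (state, v.size, float(v.mean()), float((v > 0).mean()), v.size >= min_cells)
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=["state", "n_cells", "mean_normalized", "detection_fraction", "testable"],
    )

    test_rows = []
    testable = [s for s in by_state if by_state[s].size >= min_cells]
    for a, b in itertools.combinations(sorted(testable), 2):
        stat, p = scipy.stats.mannwhitneyu(
            by_state[a], by_state[b], alternative="two-sided"
        )
        test_rows.append((a, b, float(stat), float(p)))
    tests = pd.DataFrame(test_rows, columns=["state_a", "state_b", "statistic", "p_value"])
    if not tests.empty:
        tests["adjusted_p"] = multipletests(tests["p_value"], method="fdr_bh")[1]
    else:
        tests["adjusted_p"] = pd.Series(dtype=float)
    return summary, tests


def plot_dor_dotplot(table: pd.DataFrame, path, k: int = 5) -> None:
    """Dot plot of top-k DOR per feature: x = DOR, y = group, colour =
    DOR, size = in-group detection fraction."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    top = rank_sources(table, k=k)
    fig, axis = plt.subplots(figsize=(5, max(2, 0.4 * len(top))))
    labels = top["feature"] + " / " + top["group"]
    sc = axis.scatter(top["dor"], labels, s=20 + 300 * top["detection_in"],
                      c=top["dor"], cmap="viridis")
    axis.set_xlabel("diagnostic odds ratio")
    fig.colorbar(sc, ax=axis, label="DOR")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
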