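"""miRNA-positive vs miRNA-negative subcluster analysis.

The cells of a miRNA's source group are partitioned by detection status
of that miRNA. Differential expression between the subclusters uses a
two-sided Wilcoxon rank-sum test per gene on normalized values, with

    log2FC = log2((mean_pos + 1) / (mean_neg + 1))

where the means are taken on the de-logged normalized (CP10K) scale.
A gene is a DEG when raw p < 0.05 and |log2FC| > 1 (BH-adjusted p is
reported alongside). Downregulated genes in the miRNA-positive
subcluster are compared against the miRNA's predicted targets, and
functional gene sets are scored per cell as the set's mean normalized
expression minus that of expression-matched control genes drawn from
average-expression bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .cellular_source import binarize
from .sc_core import merge_subtype_groups

logger = logging.getLogger(__name__)

DEG_P_THRESHOLD = 0.05
DEG_LOG2FC_THRESHOLD = 1.0

#: significance cutpoints -> star codes, checked in order
STAR_CUTPOINTS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


@dataclass
class SubclusterSplit:
    feature: str
    source_group: str
    positive_cells: np.ndarray
    negative_cells: np.ndarray

    @property
    def n_positive(self) -> int:
        return self.positive_cells.size

    @property
    def n_negative(self) -> int:
        return self.negative_cells.size


def split_by_positivity(
    adata: ad.AnnData,
    feature: str,
    source_group: str,
    level: str = "cell_subtype",
) -> SubclusterSplit:
    """Partition a source group's cells by detection of one feature.

    A degenerate split (all-positive or all-negative) is an error because
    the downstream two-sample statistics are undefined.
    """
    groups = merge_subtype_groups(adata, level)
    if source_group not in groups:
        raise ValueError(f"unknown source group {source_group!r}")
    idx = groups[source_group]
    if idx.size == 0:
        raise ValueError(f"source group {source_group!r} is empty")
    det = binarize(adata, feature)[idx]
    if det.all() or not det.any():
        raise ValueError(
            f"degenerate split: {feature} is "
            f"{'detected in every' if det.all() else 'absent from all'} "
            f"cell(s) of {source_group}"
        )
    return SubclusterSplit(
        feature=feature,
        source_group=source_group,
        positive_cells=idx[det],
        negative_cells=idx[~det],
    )


def _normalized_dense(adata: ad.AnnData, rows: np.ndarray) -> np.ndarray:
    if "normalized" not in adata.layers:
        raise ValueError("normalized layer required; run normalize() first")
    m = adata.layers["normalized"][rows, :]
    return m.toarray() if sp.issparse(m) else np.asarray(m)


def differential_expression(adata: ad.AnnData, split: SubclusterSplit) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between positive and negative subclusters.

    Returns one row per gene: log2_fc (positive = higher in the positive
    subcluster), raw two-sided p, BH-adjusted p, direction, and the DEG
    flag at the raw-p < 0.05 and |log2FC| > 1 thresholds. Genes constant
    across both subclusters get p = 1 by convention. Both subclusters
    must have at least 3 cells.
    """
    if split.n_positive < 3 or split.n_negative < 3:
        raise ValueError(
            f"both subclusters need >= 3 cells "
            f"(have {split.n_positive} positive, {split.n_negative} negative)"
        )
    pos = _normalized_dense(adata, split.positive_cells)
    neg = _normalized_dense(adata, split.negative_cells)

    # de-logged normalized (CP10K) means, +1 pseudocount
    mean_pos = np.expm1(pos).mean(axis=0)
    mean_neg = np.expm1(neg).mean(axis=0)
    log2_fc = np.log2((mean_pos + 1) / (mean_neg + 1))

    constant = np.all(pos == pos[0:1, :], axis=0) & np.all(neg == pos[0:1, :], axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = scipy.stats.mannwhitneyu(pos, neg, axis=0, alternative="two-sided")
    p = np.where(constant | ~np.isfinite(p), 1.0, p)

    adj = multipletests(p, method="fdr_bh")[1]
    is_deg = (p < DEG_P_THRESHOLD) & (np.abs(log2_fc) > DEG_LOG2FC_THRESHOLD)
    return pd.DataFrame(
        {
            "gene": adata.var_names,
            "log2_fc": log2_fc,
            "p_value": p,
            "adjusted_p": adj,
            "direction": np.where(log2_fc >= 0, "up", "down"),
            "is_deg": is_deg,
        }
    )


@dataclass
class OverlapSummary:
    feature: str
    direction: str
    degs: set = field(default_factory=set)
    targets: set = field(default_factory=set)

    @property
    def overlap(self) -> set:
        return self.degs & self.targets

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "direction": self.direction,
            "n_degs": len(self.degs),
            "n_predicted_targets": len(self.targets),
            "n_overlap": len(self.overlap),
            "degs": sorted(self.degs),
            "predicted_targets": sorted(self.targets),
            "overlap": sorted(self.overlap),
        }


def target_overlap(
    degs: pd.DataFrame,
    interactions: pd.DataFrame,
    feature: str,
    direction: str = "down",
) -> OverlapSummary:
    """Overlap of directional DEGs with a miRNA's predicted targets.

    By default compares the genes downregulated in the miRNA-positive
    subcluster (the expected footprint of miRNA repression) with the
    feature's targets in the interaction set; Venn-ready counts and
    member lists are returned.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if feature not in set(interactions["mirna"]):
        raise ValueError(f"{feature!r} not present in the interaction set")
    deg_genes = set(
        degs.loc[degs["is_deg"] & (degs["direction"] == direction), "gene"]
    )
    targets = set(interactions.loc[interactions["mirna"] == feature, "target"])
    return OverlapSummary(feature=feature, direction=direction, degs=deg_genes, targets=targets)


def module_score(
    adata: ad.AnnData,
    gene_set: set[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    control_genes: set[str] | None = None,
) -> np.ndarray:
    """Per-cell gene-set score: set mean minus binned-control mean.

    Genes are binned into ``n_bins`` equal-frequency bins by average
    normalized expression across all cells; each set gene contributes
    ``n_ctrl`` control genes drawn from its bin (with replacement when the
    bin is smaller than ``n_ctrl``). The score of a cell is the mean
    normalized expression of the set genes minus the mean over the pooled
    control draws. Deterministic under a fixed seed. Genes absent from
    the dataset are dropped with a warning; an empty intersection is an
    error. ``control_genes`` overrides the bins with an explicit pool
    from which the control draws are sampled (used for calibration
    checks, e.g. scoring a set against its own pool).
    """
    present = [g for g in sorted(gene_set) if g in adata.var_names]
    missing = sorted(gene_set - set(present))
    if not present:
        raise ValueError(f"no gene-set members found in the dataset: missing {missing[:5]}")
    if missing:
        logger.warning("dropping %d set genes absent from the dataset (e.g. %s)",
                       len(missing), missing[:3])

    expr = adata.layers["normalized"] if "normalized" in adata.layers else adata.X
    expr = expr.toarray() if sp.issparse(expr) else np.asarray(expr)
    set_idx = [adata.var_names.get_loc(g) for g in present]

    rng = np.random.default_rng(seed)
    if control_genes is not None:
        pool = np.array([adata.var_names.get_loc(g) for g in sorted(control_genes)
                         if g in adata.var_names])
        if pool.size == 0:
            raise ValueError("no control genes found in the dataset")
        ctrl_idx = []
        for _ in set_idx:
            ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=pool.size < n_ctrl))
    else:
        avg = expr.mean(axis=0)
        order = scipy.stats.rankdata(avg, method="ordinal") - 1
        bins = (order * n_bins) // adata.n_vars  # equal-frequency bins
        ctrl_idx = []
        for j in set_idx:
            pool = np.flatnonzero(bins == bins[j])
            replace = pool.size < n_ctrl
            ctrl_idx.extend(rng.choice(pool, size=n_ctrl, replace=replace))
    return expr[:, set_idx].mean(axis=1) - expr[:, ctrl_idx].mean(axis=1)


def score_gene_sets(
    adata: ad.AnnData,
    collection_sets: dict[str, set[str]],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Module scores for several gene sets; cells x sets DataFrame."""
    cols = {}
    for name, members in collection_sets.items():
        cols[name] = module_score(adata, members, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    return pd.DataFrame(cols, index=adata.obs_names)


def stars(p: float) -> str:
    """Map a p-value to the conventional significance stars."""
    for cut, code in STAR_CUTPOINTS:
        if p < cut:
            return code
    return "ns"


def compare_scores(scores: pd.DataFrame, split: SubclusterSplit) -> pd.DataFrame:
    """Positive-vs-negative comparison of module scores per gene set.

    Two-sided Wilcoxon rank-sum per set with BH adjustment across sets;
    the star code is derived from the raw p at the conventional
    cutpoints. Both subclusters must have at least 3 cells.
    """
    if split.n_positive < 3 or split.n_negative < 3:
        raise ValueError("both subclusters need >= 3 cells")
    rows = []
    for name in scores.columns:
        a = scores.iloc[split.positive_cells][name].to_numpy()
        b = scores.iloc[split.negative_cells][name].to_numpy()
        if np.all(a == a[0]) and np.all(b == a[0]):
            stat, p = float(a.size * b.size) / 2.0, 1.0
        else:
            stat, p = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append((name, float(a.mean()), float(b.mean()), float(stat), float(p)))
    out = pd.DataFrame(
        rows, columns=["gene_set", "mean_positive", "mean_negative", "statistic", "p_value"]
    )
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out["stars"] = out["p_value"].map(stars)
    return out


def plot_volcano(degs: pd.DataFrame, path) -> None:
    """Volcano plot of the subcluster DE table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axis = plt.subplots(figsize=(4, 4))
    logp = -np.log10(np.maximum(degs["p_value"], 1e-300))
    axis.scatter(degs["log2_fc"], logp, s=6, c=np.where(degs["is_deg"], "red", "grey"))
    axis.axvline(1, ls="--", lw=0.5)
    axis.axvline(-1, ls="--", lw=0.5)
    axis.axhline(-np.log10(0.05), ls="--", lw=0.5)
    axis.set_xlabel("log2 fold change (positive vs negative)")
    axis.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_violin(scores: pd.DataFrame, split: SubclusterSplit, path) -> None:
    """Violin plots of module scores by subcluster, with stars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comp = compare_scores(scores, split)
    n = len(scores.columns)
    fig, axes = plt.subplots(1, n, figsize=(2.2 * n, 3), squeeze=False)
    for axis, name in zip(axes[0], scores.columns):
        a = scores.iloc[split.positive_cells][name]
        b = scores.iloc[split.negative_cells][name]
        axis.violinplot([a, b], showmeans=True)
        axis.set_xticks([1, 2], ["pos", "neg"])
        star = comp.loc[comp["gene_set"] == name, "stars"].iloc[0]
        axis.set_title(f"{name}\n{star}", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
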