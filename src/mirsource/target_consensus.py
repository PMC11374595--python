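"""Consensus miRNA->mRNA interaction filtering.

A predicted interaction is retained when at least ``min_sources`` distinct
prediction databases report it. Experimentally validated interactions are
flagged, and validated-only pairs are admitted with zero prediction
support (union semantics): predicted and validated edges are typed
separately downstream, with validated taking precedence when both hold.
Finally the interaction set is intersected with the text-mined gene lists
so that every retained edge connects a mined miRNA to a mined mRNA.

Scores are carried through (mean of per-source descending ranks) for
ordering only; filtering uses source counts alone.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .literature_catalog import normalize_symbol
from .synthetic_data import DEFAULT_SOURCES

INTERACTION_COLUMNS = ["mirna", "target", "n_sources", "validated", "mean_rank"]


def _empty_interactions() -> pd.DataFrame:
    return pd.DataFrame(columns=INTERACTION_COLUMNS).astype(
        {"n_sources": int, "validated": bool, "mean_rank": float}
    )


def load_predictions(directory: str | Path) -> pd.DataFrame:
    """Read every per-source prediction TSV in a directory into one long
    table (source = file stem)."""
    frames = []
    for path in sorted(Path(directory).glob("*.tsv")):
        df = pd.read_csv(path, sep="\t")
        df.insert(0, "source", path.stem)
        frames.append(df)
    if not frames:
        raise ValueError(f"no prediction TSVs found in {directory}")
    return pd.concat(frames, ignore_index=True)


def consensus_filter(
    predictions: pd.DataFrame,
    min_sources: int = 2,
    allowed_sources: tuple[str, ...] = DEFAULT_SOURCES,
) -> pd.DataFrame:
    """Keep (miRNA, target) pairs reported by >= min_sources databases.

    Parameters
    ----------
    predictions
        Long table with columns ``source, mirna, target`` and optionally
        ``score``. Duplicate (source, mirna, target) rows collapse to one.
    min_sources
        Distinct-source support threshold (>= 1).
    allowed_sources
        The configured prediction-source set; any other source name is a
        hard error.

    Returns
    -------
    Interaction table (mirna, target, n_sources, validated=False,
    mean_rank). ``mean_rank`` is the mean of the edge's within-source
    ranks by descending score (NaN when scores are absent).
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    unknown = set(predictions["source"]) - set(allowed_sources)
    if unknown:
        raise ValueError(f"unknown prediction source(s): {sorted(unknown)}")
    if predictions.empty:
        return _empty_interactions()

    pred = predictions.copy()
    pred["mirna"] = pred["mirna"].map(normalize_symbol)
    pred["target"] = pred["target"].map(normalize_symbol)
    pred = pred.drop_duplicates(subset=["source", "mirna", "target"])
    if "score" in pred.columns:
        pred["rank_in_source"] = pred.groupby("source")["score"].rank(
            ascending=False, method="average"
        )
    else:
        pred["rank_in_source"] = float("nan")

    agg = (
        pred.groupby(["mirna", "target"], sort=True)
        .agg(n_sources=("source", "nunique"), mean_rank=("rank_in_source", "mean"))
        .reset_index()
    )
    kept = agg[agg["n_sources"] >= min_sources].reset_index(drop=True)
    kept["validated"] = False
    return kept[INTERACTION_COLUMNS]


def flag_validated(interactions: pd.DataFrame, validated_table: pd.DataFrame) -> pd.DataFrame:
    """Flag consensus edges present in the validated table; validated-only
    edges are added with n_sources=0 (union semantics)."""
    out = interactions.copy()
    if validated_table.empty:
        out["validated"] = False
        return out
    val = validated_table.copy()
    val["mirna"] = val["mirna"].map(normalize_symbol)
    val["target"] = val["target"].map(normalize_symbol)
    val_pairs = set(zip(val["mirna"], val["target"]))

    have = set(zip(out["mirna"], out["target"]))
    out["validated"] = [pair in val_pairs for pair in zip(out["mirna"], out["target"])]
    extra = sorted(val_pairs - have)
    if extra:
        add = pd.DataFrame(extra, columns=["mirna", "target"])
        add["n_sources"] = 0
        add["validated"] = True
        add["mean_rank"] = float("nan")
        out = pd.concat([out, add[INTERACTION_COLUMNS]], ignore_index=True)
    return out.sort_values(["mirna", "target"], kind="mergesort").reset_index(drop=True)


def intersect_with_catalog(
    interactions: pd.DataFrame,
    mined_mrnas: set[str],
    mined_mirnas: set[str],
) -> pd.DataFrame:
    """Keep edges whose target is a mined mRNA and miRNA a mined miRNA."""
    keep = interactions["target"].isin(mined_mrnas) & interactions["mirna"].isin(mined_mirnas)
    return interactions[keep].reset_index(drop=True)


def build_interactions(
    predictions: pd.DataFrame,
    validated_table: pd.DataFrame,
    mined_mrnas: set[str],
    mined_mirnas: set[str],
    min_sources: int = 2,
    allowed_sources: tuple[str, ...] = DEFAULT_SOURCES,
) -> pd.DataFrame:
    """Full interaction-set construction: consensus filter, validated
    flagging (union), then intersection with the mined gene lists."""
    consensus = consensus_filter(predictions, min_sources, allowed_sources)
    flagged = flag_validated(consensus, validated_table)
    return intersect_with_catalog(flagged, mined_mrnas, mined_mirnas)
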