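"""Gene-mention catalog: ingest literature-annotation exports, keep human
genes, annotate biotypes, and rank per-disease mention frequencies.

Frequency is counted as the number of *distinct documents* mentioning a
gene for a disease query, which is robust to repeated mentions within one
abstract. Symbols are upper-cased before joining to the biotype map,
except miRNA-style symbols (``hsa-...``), which keep their conventional
casing.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .synthetic_data import HUMAN_SPECIES

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "miRNA", "lncRNA", "other")

MENTION_COLUMNS = ("document_id", "gene_symbol", "species", "disease_label")


def normalize_symbol(symbol: str) -> str:
    """Upper-case a gene symbol unless it follows the miRNA convention."""
    s = symbol.strip()
    return s if s.lower().startswith("hsa-") else s.upper()


def load_mentions(
    path: str | Path,
    disease_labels: list[str] | tuple[str, ...],
    species: str = HUMAN_SPECIES,
) -> pd.DataFrame:
    """Read a mention TSV and keep human rows with known disease labels.

    Parameters
    ----------
    path
        Tab-delimited file with columns ``document_id, gene_symbol,
        species, disease_label``.
    disease_labels
        The configured disease queries; rows with other labels are
        excluded (the count is logged).
    species
        Taxon label treated as human origin.

    Returns
    -------
    DataFrame of mention records (one row per raw mention).

    Raises
    ------
    ValueError
        If a required column is missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MENTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mention file {path} is missing required column(s): {missing}")
    if df.empty:
        logger.warning("mention file %s is empty", path)
        return df

    n = len(df)
    malformed = df[list(MENTION_COLUMNS)].isna().any(axis=1)
    if malformed.any():
        logger.warning("dropping %d malformed mention rows", int(malformed.sum()))
        df = df[~malformed]
    nonhuman = df["species"] != species
    if nonhuman.any():
        logger.info("dropping %d non-human mention rows", int(nonhuman.sum()))
        df = df[~nonhuman]
    unknown = ~df["disease_label"].isin(disease_labels)
    if unknown.any():
        logger.info("dropping %d rows with unknown disease labels", int(unknown.sum()))
        df = df[~unknown]
    logger.info("loaded %d/%d mention rows from %s", len(df), n, path)
    return df.reset_index(drop=True)


def load_biotype_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV (gene_symbol, biotype) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_symbol", "biotype"):
        if col not in df.columns:
            raise ValueError(f"biotype file {path} is missing column {col!r}")
    return {normalize_symbol(s): b for s, b in zip(df["gene_symbol"], df["biotype"])}


def build_catalog(records: pd.DataFrame, biotype_map: dict[str, str]) -> pd.DataFrame:
    """Aggregate mention records into the per-disease frequency catalog.

    Frequency of a (gene, disease) pair is the number of distinct
    documents mentioning it. Symbols missing from ``biotype_map`` are
    assigned biotype ``other`` so totals are conserved.
    """
    if records.empty:
        return pd.DataFrame(columns=["gene_symbol", "disease_label", "frequency", "biotype"])
    rec = records.copy()
    rec["gene_symbol"] = rec["gene_symbol"].map(normalize_symbol)
    grouped = (
        rec.groupby(["gene_symbol", "disease_label"], sort=True)["document_id"]
        .nunique()
        .reset_index(name="frequency")
    )
    grouped["biotype"] = grouped["gene_symbol"].map(
        lambda s: biotype_map.get(s, "other")
    )
    grouped.loc[~grouped["biotype"].isin(BIOTYPES), "biotype"] = "other"
    return grouped


def top_k(
    catalog: pd.DataFrame,
    disease_label: str,
    biotype: str | None = None,
    k: int = 10,
) -> pd.DataFrame:
    """Top-k genes for one disease, descending by frequency.

    Ties are broken lexicographically by symbol (stable). ``biotype=None``
    ranks across all biotypes; ``k`` larger than the table returns the
    full ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if disease_label not in set(catalog["disease_label"]):
        raise ValueError(f"unknown disease label {disease_label!r}")
    sub = catalog[catalog["disease_label"] == disease_label]
    if biotype is not None:
        sub = sub[sub["biotype"] == biotype]
    ranked = sub.sort_values(
        ["frequency", "gene_symbol"], ascending=[False, True], kind="mergesort"
    )
    return ranked.head(k).reset_index(drop=True)


def biotype_summary(catalog: pd.DataFrame, disease_label: str) -> dict[str, int]:
    """Distinct-gene counts per biotype for one disease; sums to the
    disease's distinct gene count."""
    sub = catalog[catalog["disease_label"] == disease_label]
    counts = sub.groupby("biotype")["gene_symbol"].nunique().to_dict()
    return {b: int(counts.get(b, 0)) for b in BIOTYPES}


def mined_sets(catalog: pd.DataFrame, disease_label: str) -> tuple[set[str], set[str]]:
    """(mined mRNA symbols, mined miRNA symbols) for one disease — the
    intersection lists used by the target-consensus filter."""
    sub = catalog[catalog["disease_label"] == disease_label]
    mrnas = set(sub.loc[sub["biotype"] == "protein_coding", "gene_symbol"])
    mirnas = set(sub.loc[sub["biotype"] == "miRNA", "gene_symbol"])
    return mrnas, mirnas
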