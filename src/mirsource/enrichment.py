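"""Over-representation analysis of gene lists against GMT gene-set
collections.

The test is the one-sided hypergeometric upper tail: with a universe of
``N`` genes of which ``K`` belong to the set, and a query of ``n`` genes,
the p-value is P(X >= overlap) for X ~ Hypergeom(N, K, n). P-values are
Benjamini-Hochberg adjusted across the sets of a collection. The
background universe is an explicit parameter (by default the mRNA side of
the interaction set under study).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str]
    universe: set[str]

    @classmethod
    def from_gmt(cls, path: str | Path, universe: set[str] | None = None) -> "GeneSetCollection":
        """Parse a GMT file (name, description, members...). If a universe
        is given, members are restricted to it; sets emptied by the
        restriction are dropped."""
        sets: dict[str, set[str]] = {}
        descriptions: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            name, desc, *members = fields
            members_set = {m for m in members if m}
            if universe is not None:
                members_set &= universe
            if members_set:
                sets[name] = members_set
                descriptions[name] = desc
        if universe is None:
            universe = set().union(*sets.values()) if sets else set()
        return cls(sets=sets, descriptions=descriptions, universe=universe)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        sets = {n: s & universe for n, s in self.sets.items()}
        sets = {n: s for n, s in sets.items() if s}
        return GeneSetCollection(
            sets=sets,
            descriptions={n: self.descriptions[n] for n in sets},
            universe=universe,
        )


def hypergeom_pvalue(overlap: int, set_size: int, query_size: int, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= overlap)."""
    if universe_size <= 0:
        raise ValueError("empty universe")
    if query_size == 0 or set_size == 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def ora(
    query: set[str],
    collection: GeneSetCollection,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Over-representation of a query gene list against every set.

    Query genes outside the universe are dropped with a warning. Returns a
    DataFrame (set_name, overlap, set_size, query_size, universe_size,
    p_value, adjusted_p) sorted by adjusted then raw p. Sets with overlap
    below ``min_overlap`` are excluded before adjustment.
    """
    universe = collection.universe
    if not universe:
        raise ValueError("empty universe")
    outside = query - universe
    if outside:
        logger.warning(
            "dropping %d query genes outside the universe (e.g. %s)",
            len(outside), sorted(outside)[:3],
        )
    q = query & universe
    rows = []
    for name, members in collection.sets.items():
        ov = len(q & members)
        if ov < min_overlap:
            continue
        rows.append((name, ov, len(members), len(q), len(universe),
                     hypergeom_pvalue(ov, len(members), len(q), len(universe))))
    result = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "p_value"],
    )
    if result.empty:
        result["adjusted_p"] = pd.Series(dtype=float)
        return result
    result["adjusted_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
    return result.sort_values(
        ["adjusted_p", "p_value", "set_name"], kind="mergesort"
    ).reset_index(drop=True)


def enrich_top_mirnas(
    ranking: pd.DataFrame,
    interactions: pd.DataFrame,
    collection: GeneSetCollection,
    top_n: int = 5,
    top_terms: int = 5,
) -> dict[str, pd.DataFrame]:
    """ORA of each top-ranked miRNA's target set.

    For each of the first ``top_n`` miRNAs of an average-rank
    prioritization, runs ORA of its targets and keeps the ``top_terms``
    best-adjusted terms. A miRNA with no targets yields an empty table
    with a warning.
    """
    if top_n > len(ranking):
        raise ValueError(f"top_n={top_n} exceeds ranking size {len(ranking)}")
    results: dict[str, pd.DataFrame] = {}
    for mirna in ranking["mirna"].head(top_n):
        targets = set(interactions.loc[interactions["mirna"] == mirna, "target"])
        if not targets:
            logger.warning("miRNA %s has no targets in the interaction set", mirna)
            results[mirna] = ora(set(), collection).head(0)
            continue
        results[mirna] = ora(targets, collection).head(top_terms)
    return results
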