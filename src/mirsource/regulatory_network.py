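"""Bipartite miRNA-mRNA regulatory network: construction, bookkeeping
statistics, frequency-degree correlation, and average-rank miRNA
prioritization.

The graph is strictly bipartite (miRNA side / mRNA side); each edge is
typed ``predicted`` or ``validated`` (validated wins when both hold,
matching the red-over-grey edge colouring convention of network figures).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class NetworkStats:
    n_mirna: int
    n_mrna: int
    n_edges_predicted: int
    n_edges_validated: int

    @property
    def n_edges(self) -> int:
        return self.n_edges_predicted + self.n_edges_validated

    @property
    def fraction_validated(self) -> float:
        return self.n_edges_validated / self.n_edges if self.n_edges else float("nan")


def build_network(interactions: pd.DataFrame) -> nx.Graph:
    """Build the bipartite graph from an interaction table.

    Nodes carry ``biotype`` ("miRNA"/"mRNA"); edges carry ``support``
    ("validated" if flagged, else "predicted"). A symbol appearing on both
    sides, or a self-edge, violates bipartiteness and is a hard error.
    """
    mirnas = set(interactions["mirna"])
    targets = set(interactions["target"])
    overlap = mirnas & targets
    if overlap:
        raise ValueError(f"non-bipartite input: symbols on both sides: {sorted(overlap)[:5]}")

    g = nx.Graph()
    for row in interactions.itertuples(index=False):
        if row.mirna == row.target:
            raise ValueError(f"self-edge {row.mirna}")
        g.add_node(row.mirna, biotype="miRNA")
        g.add_node(row.target, biotype="mRNA")
        g.add_edge(row.mirna, row.target,
                   support="validated" if row.validated else "predicted")
    return g


def network_stats(net: nx.Graph) -> NetworkStats:
    """Node and edge tallies by biotype and support type."""
    biotypes = nx.get_node_attributes(net, "biotype")
    n_mirna = sum(1 for b in biotypes.values() if b == "miRNA")
    n_mrna = sum(1 for b in biotypes.values() if b == "mRNA")
    n_val = sum(1 for *_, d in net.edges(data=True) if d["support"] == "validated")
    return NetworkStats(
        n_mirna=n_mirna,
        n_mrna=n_mrna,
        n_edges_predicted=net.number_of_edges() - n_val,
        n_edges_validated=n_val,
    )


def mirna_degrees(net: nx.Graph) -> dict[str, int]:
    biotypes = nx.get_node_attributes(net, "biotype")
    return {n: d for n, d in net.degree() if biotypes[n] == "miRNA"}


def _paired_frequency_degree(
    net: nx.Graph, catalog: pd.DataFrame, disease_label: str | None
) -> pd.DataFrame:
    labels = catalog["disease_label"].unique()
    if disease_label is None:
        if len(labels) != 1:
            raise ValueError(
                "catalog covers several diseases; pass disease_label explicitly"
            )
        disease_label = labels[0]
    sub = catalog[
        (catalog["disease_label"] == disease_label) & (catalog["biotype"] == "miRNA")
    ]
    freq = dict(zip(sub["gene_symbol"], sub["frequency"]))
    degs = mirna_degrees(net)
    rows = [(m, freq[m], d) for m, d in sorted(degs.items()) if m in freq]
    return pd.DataFrame(rows, columns=["mirna", "frequency", "degree"])


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman rho, by full
    enumeration of y-permutations. Feasible for n <= 8."""
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, np.asarray(perm))[0, 1]
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def frequency_degree_correlation(
    net: nx.Graph,
    catalog: pd.DataFrame,
    disease_label: str | None = None,
    log_transform: bool = False,
    method: str = "approx",
) -> tuple[float, float, int]:
    """Spearman correlation between mention frequency and network degree.

    Returns ``(rho, p_value, n)`` over miRNAs present in both the catalog
    (for the given disease) and the network. ``log_transform`` applies
    log10(x+1) to both variables; because Spearman is rank-based this
    changes plots only, never rho. ``method="exact"`` enumerates all
    permutations (n <= 8 only); the default uses the large-n t
    approximation.
    """
    pairs = _paired_frequency_degree(net, catalog, disease_label)
    n = len(pairs)
    if n < 3:
        raise ValueError(f"need >= 3 miRNAs in both catalog and network, have {n}")
    x = pairs["frequency"].to_numpy(float)
    y = pairs["degree"].to_numpy(float)
    if log_transform:
        x = np.log10(x + 1)
        y = np.log10(y + 1)
    rho, p = scipy.stats.spearmanr(x, y)
    if method == "exact":
        if n > 8:
            raise ValueError("exact permutation p-value supported for n <= 8 only")
        p = _exact_spearman_pvalue(x, y)
    elif method != "approx":
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(p), n


def rank_mirnas(
    net: nx.Graph,
    catalog: pd.DataFrame,
    k: int = 5,
    disease_label: str | None = None,
    raw_average: bool = False,
) -> pd.DataFrame:
    """Prioritize miRNAs by the average rank of mention frequency and
    network degree.

    Rank 1 is the largest value; ties take mid-ranks. Final order is
    ascending mean rank, ties broken by higher frequency then symbol.
    ``raw_average`` switches to averaging the raw values instead of the
    ranks (a scale-sensitive variant kept behind a flag).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = _paired_frequency_degree(net, catalog, disease_label)
    if pairs.empty:
        return pairs.assign(rank_frequency=[], rank_degree=[], mean_rank=[], final_rank=[])
    # rankdata ranks ascending; negate so the largest value gets rank 1
    pairs["rank_frequency"] = scipy.stats.rankdata(-pairs["frequency"], method="average")
    pairs["rank_degree"] = scipy.stats.rankdata(-pairs["degree"], method="average")
    if raw_average:
        score = -(pairs["frequency"] + pairs["degree"]) / 2.0
    else:
        score = (pairs["rank_frequency"] + pairs["rank_degree"]) / 2.0
    pairs["mean_rank"] = (pairs["rank_frequency"] + pairs["rank_degree"]) / 2.0
    order = np.lexsort(
        (pairs["mirna"], -pairs["frequency"].to_numpy(float), score.to_numpy(float))
    )
    pairs = pairs.iloc[order].reset_index(drop=True)
    pairs["final_rank"] = np.arange(1, len(pairs) + 1)
    return pairs.head(k)


def export_network(net: nx.Graph, path: str | Path, format: str = "edgelist") -> None:
    """Write the graph as a GEXF file or an attribute-carrying edge-list
    TSV (mirna, target, support) that round-trips exactly."""
    path = Path(path)
    if format == "gexf":
        nx.write_gexf(net, path)
    elif format == "edgelist":
        biotypes = nx.get_node_attributes(net, "biotype")
        rows = []
        for u, v, d in net.edges(data=True):
            mir, tgt = (u, v) if biotypes[u] == "miRNA" else (v, u)
            rows.append((mir, tgt, d["support"]))
        pd.DataFrame(sorted(rows), columns=["mirna", "target", "support"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_edge_list(path: str | Path) -> nx.Graph:
    """Rebuild a network from an exported edge-list TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        return nx.Graph()
    df = df.rename(columns={"support": "validated"})
    df["validated"] = df["validated"] == "validated"
    return build_network(df[["mirna", "target", "validated"]])


def plot_frequency_degree(
    net: nx.Graph,
    catalog: pd.DataFrame,
    path: str | Path,
    disease_label: str | None = None,
) -> None:
    """Scatter of log10(frequency+1) vs log10(degree+1) with the Spearman
    rho annotated (presentation of the correlation, not its computation)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pairs = _paired_frequency_degree(net, catalog, disease_label)
    rho, p, n = frequency_degree_correlation(net, catalog, disease_label)
    fig, axis = plt.subplots(figsize=(4, 4))
    axis.scatter(np.log10(pairs["frequency"] + 1), np.log10(pairs["degree"] + 1), s=12)
    axis.set_xlabel("log10(mention frequency + 1)")
    axis.set_ylabel("log10(network degree + 1)")
    axis.set_title(f"Spearman r={rho:.2f}, p={p:.2g}, n={n}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
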