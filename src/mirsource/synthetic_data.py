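"""Synthetic inputs with planted ground truth for the whole pipeline.

Every downstream stage (literature catalog, target consensus, network
statistics, DOR cellular sourcing, subcluster DE) consumes tables or
matrices this module can generate with known, recoverable structure:

* gene-mention records with power-law mention frequencies,
* multi-source miRNA->target prediction tables with a planted consensus
  edge set and single-source decoys, plus a validated subset,
* negative-binomial cell x gene count matrices with planted cell-type
  specific miRNA detection and planted differentially expressed genes.

Mention frequency and regulatory-network degree are coupled per miRNA
through a Gaussian copula so that the frequency-degree Spearman
correlation downstream recovers a configured value.
"""

from __future__ import annotations

import dataclasses
import functools
import json
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.special
import scipy.stats

HUMAN_SPECIES = "Homo sapiens"

#: Canonical prediction-source names (five prediction databases).
DEFAULT_SOURCES = ("DIANA", "TargetScan", "PicTar", "miRanda", "miRDB")

#: Familiar miRNA symbols used for the first few simulated miRNAs so the
#: planted examples read naturally; the rest are generic.
_MIRNA_SEED_NAMES = (
    "hsa-miR-145",
    "hsa-miR-21",
    "hsa-miR-146a",
    "hsa-miR-155",
    "hsa-miR-223",
    "hsa-miR-142",
    "hsa-miR-29a",
    "hsa-miR-34a",
)


def _default_cells_per_type() -> dict[str, int]:
    return {"myofibroblast": 250, "enterocyte": 250, "T cell": 250}


def _default_planted_pairs() -> list[tuple[str, str, float, float]]:
    return [("hsa-miR-145", "myofibroblast", 0.6, 0.02)]


def _default_planted_de() -> list[tuple[str, float, str]]:
    return [(f"GENE{i:04d}", 4.0, "down") for i in range(1, 21)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-study generator.

    Defaults describe a small but statistically realistic instance: three
    cell types of 250 cells, sparse negative-binomial counts, one planted
    miRNA/cell-type pair (detection 0.6 in-type vs 0.02 elsewhere) and 20
    genes planted 4-fold down in miRNA-positive cells.
    """

    seed: int = 0
    n_genes_protein: int = 800
    n_mirnas: int = 40
    n_lncrnas: int = 60
    mention_powerlaw_exponent: float = 2.0
    n_prediction_sources: int = 5
    per_source_coverage: float = 0.6
    validated_fraction: float = 0.2
    n_cells_per_type: dict[str, int] = field(default_factory=_default_cells_per_type)
    disease_states: tuple[str, ...] = ("Heal", "NonI", "Infl")
    nb_mean: float = 0.3
    nb_dispersion: float = 0.5
    planted_specific_pairs: list[tuple[str, str, float, float]] = field(
        default_factory=_default_planted_pairs
    )
    planted_de: list[tuple[str, float, str]] = field(default_factory=_default_planted_de)
    mito_gene_fraction: float = 0.05
    # --- plumbing beyond the headline knobs ---
    disease_labels: tuple[str, ...] = ("IBD", "CD", "UC")
    frequency_degree_rho: float = 0.6
    min_targets_per_mirna: int = 2
    max_targets_per_mirna: int = 30
    n_decoy_edges: int = 100
    background_mirna_detection: float = 0.01
    detected_count_rate: float = 1.0
    planted_state_shift: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.mention_powerlaw_exponent <= 1:
            raise ValueError("mention_powerlaw_exponent must be > 1")
        for name in ("per_source_coverage", "validated_fraction", "mito_gene_fraction",
                     "background_mirna_detection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes_protein", "n_mirnas", "n_prediction_sources"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_lncrnas < 0:
            raise ValueError("n_lncrnas must be >= 0")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("nb_mean and nb_dispersion must be > 0")
        if any(n <= 0 for n in self.n_cells_per_type.values()):
            raise ValueError("cell counts must be positive")
        for mir, ctype, rate_in, rate_out in self.planted_specific_pairs:
            if not (0 <= rate_out < rate_in <= 1):
                raise ValueError(
                    f"planted pair ({mir}, {ctype}): need 0 <= rate_out < rate_in <= 1"
                )
        if not -1.0 <= self.frequency_degree_rho <= 1.0:
            raise ValueError("frequency_degree_rho must be in [-1, 1]")

    # Gene pools -----------------------------------------------------------
    @property
    def source_names(self) -> tuple[str, ...]:
        if self.n_prediction_sources <= len(DEFAULT_SOURCES):
            return DEFAULT_SOURCES[: self.n_prediction_sources]
        extra = tuple(
            f"source_{i}" for i in range(len(DEFAULT_SOURCES) + 1, self.n_prediction_sources + 1)
        )
        return DEFAULT_SOURCES + extra

    @property
    def n_mito(self) -> int:
        return int(round(self.mito_gene_fraction * self.n_genes_protein))

    @property
    def protein_genes(self) -> list[str]:
        n_mito = self.n_mito
        mito = [f"MT-GENE{i:02d}" for i in range(1, n_mito + 1)]
        rest = [f"GENE{i:04d}" for i in range(1, self.n_genes_protein - n_mito + 1)]
        return rest + mito

    @property
    def mirna_genes(self) -> list[str]:
        names = list(_MIRNA_SEED_NAMES[: self.n_mirnas])
        names += [f"hsa-miR-sim{i}" for i in range(len(names) + 1, self.n_mirnas + 1)]
        return names

    @property
    def lncrna_genes(self) -> list[str]:
        return [f"LINC{i:04d}" for i in range(1, self.n_lncrnas + 1)]

    def biotype_map(self) -> dict[str, str]:
        m = {g: "protein_coding" for g in self.protein_genes}
        m.update({g: "miRNA" for g in self.mirna_genes})
        m.update({g: "lncRNA" for g in self.lncrna_genes})
        return m


@dataclass
class GroundTruth:
    """Planted structure the pipeline is expected to recover."""

    true_specific_pairs: set = field(default_factory=set)
    true_de_genes: set = field(default_factory=set)
    true_de_direction: dict = field(default_factory=dict)
    true_consensus_edges: set = field(default_factory=set)
    frequency_degree_rho: float = 0.0
    n_validated: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_specific_pairs": sorted(self.true_specific_pairs),
            "true_de_genes": sorted(self.true_de_genes),
            "true_de_direction": self.true_de_direction,
            "true_consensus_edges": sorted(self.true_consensus_edges),
            "frequency_degree_rho": self.frequency_degree_rho,
            "n_validated": self.n_validated,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            true_specific_pairs={tuple(p) for p in d["true_specific_pairs"]},
            true_de_genes=set(d["true_de_genes"]),
            true_de_direction=d["true_de_direction"],
            true_consensus_edges={tuple(e) for e in d["true_consensus_edges"]},
            frequency_degree_rho=d["frequency_degree_rho"],
            n_validated=d["n_validated"],
        )


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence((config.seed, stream)))


_ZIPF_SUPPORT_CAP = 100_000


def _zipf_quantile(u: np.ndarray, exponent: float) -> np.ndarray:
    """Vectorized zipf quantile via grid inversion of the CDF.

    The support is capped at 100k (tail mass ~1e-5 at exponent 2), which
    scipy's generic discrete ppf cannot handle efficiently for u near 1.
    """
    ks = np.arange(1, _ZIPF_SUPPORT_CAP + 1)
    pmf = ks**-float(exponent) / scipy.special.zeta(exponent)
    cdf = np.cumsum(pmf)
    return ks[np.minimum(np.searchsorted(cdf, u), _ZIPF_SUPPORT_CAP - 1)]


def _coupled_mirna_margins(config: SimulationConfig, rng: np.random.Generator):
    """Draw per-miRNA (mention frequency, target-set size) with a planted
    Spearman association via a Gaussian copula.

    For a bivariate normal with Pearson correlation r the population
    Spearman rho is (6/pi)*asin(r/2); inverting gives r = 2*sin(pi*rho/6).
    Monotone margin transforms preserve Spearman up to ties.
    """
    rho = config.frequency_degree_rho
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=config.n_mirnas)
    u = scipy.stats.norm.cdf(z)
    freqs = _zipf_quantile(u[:, 0], config.mention_powerlaw_exponent)
    lo, hi = config.min_targets_per_mirna, config.max_targets_per_mirna
    degrees = (lo + np.floor(u[:, 1] * (hi - lo + 1))).astype(int)
    degrees = np.clip(degrees, lo, hi)
    return freqs, degrees


def _mirna_frequencies_and_degrees(config: SimulationConfig):
    rng = _rng(config, 1)
    return _coupled_mirna_margins(config, rng)


@functools.lru_cache(maxsize=None)
def _population_rho_cached(
    exponent: float, lo: int, hi: int, latent_rho: float, n_mc: int
) -> float:
    cfg = SimulationConfig(
        mention_powerlaw_exponent=exponent,
        min_targets_per_mirna=lo,
        max_targets_per_mirna=hi,
        frequency_degree_rho=latent_rho,
        n_mirnas=n_mc,
    )
    rng = np.random.default_rng(987654321)  # population constant, seed-independent
    f, d = _coupled_mirna_margins(cfg, rng)
    return float(scipy.stats.spearmanr(f, d).statistic)


def population_frequency_degree_rho(config: SimulationConfig, n_mc: int = 200_000) -> float:
    """Population Spearman rho of the generative (frequency, degree) law.

    The latent copula correlation is attenuated by ties in the discrete
    power-law frequency margin, so the value the sampled rho converges to
    is computed by a large Monte Carlo draw through the same margin maps.
    This is the planted association strength recorded in GroundTruth.
    """
    return _population_rho_cached(
        config.mention_powerlaw_exponent,
        config.min_targets_per_mirna,
        config.max_targets_per_mirna,
        config.frequency_degree_rho,
        n_mc,
    )


def simulate_mentions(config: SimulationConfig) -> pd.DataFrame:
    """Generate the per-(gene, disease) mention catalog.

    Returns a DataFrame with columns ``gene_symbol, disease_label,
    frequency, biotype``; frequencies are zipf-distributed (>= 1).
    miRNA frequencies are shared across disease labels and coupled to the
    planted regulatory degree; other biotypes draw independently per
    disease.
    """
    config.validate()
    rng = _rng(config, 2)
    mirna_freqs, _ = _mirna_frequencies_and_degrees(config)

    rows = []
    a = config.mention_powerlaw_exponent
    for disease in config.disease_labels:
        for g, f in zip(config.mirna_genes, mirna_freqs):
            rows.append((g, disease, int(f), "miRNA"))
        for pool, biotype in (
            (config.protein_genes, "protein_coding"),
            (config.lncrna_genes, "lncRNA"),
        ):
            freqs = rng.zipf(a, size=len(pool))
            for g, f in zip(pool, freqs):
                rows.append((g, disease, int(f), biotype))
    return pd.DataFrame(rows, columns=["gene_symbol", "disease_label", "frequency", "biotype"])


def expand_to_records(catalog: pd.DataFrame) -> pd.DataFrame:
    """Expand a mention catalog to document-level records.

    Each (gene, disease) row of frequency f becomes f records with
    distinct document ids, so distinct-document counting downstream
    reproduces the catalog exactly.
    """
    genes = np.repeat(catalog["gene_symbol"].to_numpy(), catalog["frequency"].to_numpy())
    diseases = np.repeat(catalog["disease_label"].to_numpy(), catalog["frequency"].to_numpy())
    idx = np.concatenate([np.arange(1, f + 1) for f in catalog["frequency"]])
    doc_ids = [f"PMID:{d}:{g}:{i}" for g, d, i in zip(genes, diseases, idx)]
    return pd.DataFrame(
        {
            "document_id": doc_ids,
            "gene_symbol": genes,
            "species": HUMAN_SPECIES,
            "disease_label": diseases,
        }
    )


def simulate_predictions(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate per-source prediction tables, a validated table and truth.

    Returns ``(predictions, validated, truth)`` where ``predictions`` is a
    long DataFrame (source, mirna, target, score). Every true consensus
    edge appears in >= 2 distinct sources; decoy edges appear in exactly
    one source; the validated table is a subset of the true edges of size
    round(validated_fraction * n_true).
    """
    config.validate()
    rng = _rng(config, 3)
    _, degrees = _mirna_frequencies_and_degrees(config)
    sources = config.source_names
    n_src = len(sources)
    proteins = np.array(config.protein_genes)

    true_edges: list[tuple[str, str]] = []
    for mir, deg in zip(config.mirna_genes, degrees):
        targets = rng.choice(proteins, size=min(deg, len(proteins)), replace=False)
        true_edges.extend((mir, t) for t in targets)
    true_set = set(true_edges)

    rows = []
    for mir, tgt in true_edges:
        support = np.flatnonzero(rng.random(n_src) < config.per_source_coverage)
        while support.size < 2:
            support = np.union1d(support, rng.integers(0, n_src, size=1))
        for s in support:
            rows.append((sources[s], mir, tgt, float(rng.random())))

    # decoys: distinct non-true pairs, each supported by exactly one source
    used = set(true_set)
    n_decoys = 0
    while n_decoys < config.n_decoy_edges:
        mir = config.mirna_genes[rng.integers(0, config.n_mirnas)]
        tgt = proteins[rng.integers(0, len(proteins))]
        if (mir, tgt) in used:
            continue
        used.add((mir, tgt))
        rows.append((sources[rng.integers(0, n_src)], mir, tgt, float(rng.random())))
        n_decoys += 1

    predictions = pd.DataFrame(rows, columns=["source", "mirna", "target", "score"])
    predictions = predictions.drop_duplicates(subset=["source", "mirna", "target"])

    n_validated = int(round(config.validated_fraction * len(true_edges)))
    val_idx = rng.choice(len(true_edges), size=n_validated, replace=False)
    validated = pd.DataFrame(
        [(true_edges[i][0], true_edges[i][1], "Functional MTI") for i in sorted(val_idx)],
        columns=["mirna", "target", "evidence"],
    )

    truth = GroundTruth(
        true_consensus_edges=true_set,
        frequency_degree_rho=population_frequency_degree_rho(config),
        n_validated=n_validated,
    )
    return predictions, validated, truth


def simulate_counts(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a cell x gene count matrix with planted structure.

    Counts are negative binomial (global dispersion, per-gene log-normal
    mean scaling). Planted cell-type-specific miRNAs are detected with
    ``rate_in`` inside their cell type and ``rate_out`` elsewhere;
    non-planted miRNAs have a uniform low background detection rate.
    Planted DE genes have the configured fold change between
    miRNA-positive and miRNA-negative cells of the first planted pair's
    cell type.
    """
    config.validate()
    known_types = set(config.n_cells_per_type)
    for mir, ctype, *_ in config.planted_specific_pairs:
        if ctype not in known_types:
            raise ValueError(f"planted pair references unknown cell type {ctype!r}")
        if mir not in config.mirna_genes:
            raise ValueError(f"planted pair references unknown miRNA {mir!r}")

    rng = _rng(config, 4)
    genes = config.protein_genes + config.lncrna_genes
    mirnas = config.mirna_genes
    all_features = genes + mirnas
    n_genes = len(all_features)

    cell_types = np.concatenate(
        [np.repeat(t, n) for t, n in config.n_cells_per_type.items()]
    )
    n_cells = cell_types.size
    # two subtypes per type, randomly assigned, to exercise merging
    sub_idx = rng.integers(1, 3, size=n_cells)
    cell_subtypes = np.array([f"{t}.{i}" for t, i in zip(cell_types, sub_idx)])
    disease_state = rng.choice(config.disease_states, size=n_cells)
    barcodes = np.array([f"CELL{i:05d}" for i in range(1, n_cells + 1)])

    # NB background for ordinary genes: mu_g = nb_mean * lognormal factor
    gene_mu = config.nb_mean * rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    mu = np.broadcast_to(gene_mu, (n_cells, len(genes))).copy()

    truth = GroundTruth(frequency_degree_rho=config.frequency_degree_rho)

    # planted miRNA detection, and miRNA-positive masks per planted pair
    mirna_counts = np.zeros((n_cells, len(mirnas)), dtype=np.int64)
    positive_masks: dict[tuple[str, str], np.ndarray] = {}
    planted_mirs = {p[0] for p in config.planted_specific_pairs}
    lam = config.detected_count_rate
    state_shift = np.ones(n_cells)
    for state, factor in config.planted_state_shift.items():
        state_shift[disease_state == state] = factor
    for j, mir in enumerate(mirnas):
        if mir not in planted_mirs:
            det = rng.random(n_cells) < config.background_mirna_detection
            mirna_counts[det, j] = 1 + rng.poisson(lam, size=int(det.sum()))
    for mir, ctype, rate_in, rate_out in config.planted_specific_pairs:
        j = mirnas.index(mir)
        in_type = cell_types == ctype
        p_det = np.where(in_type, rate_in, rate_out)
        det = rng.random(n_cells) < p_det
        mirna_counts[det, j] = 1 + rng.poisson(lam * state_shift[det])
        positive_masks[(mir, ctype)] = det & in_type
        truth.true_specific_pairs.add((mir, ctype))

    # planted DE relative to the first planted pair's positive/negative split
    if config.planted_de:
        if not config.planted_specific_pairs:
            raise ValueError("planted_de requires at least one planted specific pair")
        mir0, ctype0, *_ = config.planted_specific_pairs[0]
        pos = positive_masks[(mir0, ctype0)]
        gene_index = {g: i for i, g in enumerate(genes)}
        for gene, fc, direction in config.planted_de:
            if gene not in gene_index:
                raise ValueError(f"planted DE gene {gene!r} not in gene pool")
            if direction not in ("up", "down"):
                raise ValueError("planted DE direction must be 'up' or 'down'")
            gi = gene_index[gene]
            # planted DE genes sit at the configured baseline mean so the
            # fold change, not the per-gene baseline draw, is the planted
            # experimental variable
            mu[:, gi] = config.nb_mean
            if direction == "up":
                mu[pos, gi] *= fc
            else:
                mu[pos, gi] /= fc
            truth.true_de_genes.add(gene)
            truth.true_de_direction[gene] = direction

    r = config.nb_dispersion
    counts_genes = rng.negative_binomial(r, r / (r + mu))
    counts = np.concatenate([counts_genes, mirna_counts], axis=1)

    biotype_map = config.biotype_map()
    var = pd.DataFrame(
        {
            "biotype": [biotype_map[g] for g in all_features],
            "is_mito": [g.startswith("MT-") for g in all_features],
        },
        index=pd.Index(all_features, name="symbol"),
    )
    obs = pd.DataFrame(
        {
            "cell_type": cell_types,
            "cell_subtype": cell_subtypes,
            "disease_state": disease_state,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    return adata, truth


@dataclass
class SimulationResult:
    """All generated inputs of one synthetic study, plus merged truth."""

    catalog: pd.DataFrame
    mentions: pd.DataFrame
    predictions: pd.DataFrame
    validated: pd.DataFrame
    dataset: ad.AnnData
    truth: GroundTruth


def simulate_all(config: SimulationConfig) -> SimulationResult:
    """Run every generator stage under one config and merge ground truth."""
    catalog = simulate_mentions(config)
    mentions = expand_to_records(catalog)
    predictions, validated, truth_net = simulate_predictions(config)
    dataset, truth_sc = simulate_counts(config)
    truth = GroundTruth(
        true_specific_pairs=truth_sc.true_specific_pairs,
        true_de_genes=truth_sc.true_de_genes,
        true_de_direction=truth_sc.true_de_direction,
        true_consensus_edges=truth_net.true_consensus_edges,
        frequency_degree_rho=truth_net.frequency_degree_rho,
        n_validated=truth_net.n_validated,
    )
    return SimulationResult(catalog, mentions, predictions, validated, dataset, truth)


def write_all(result: SimulationResult, outdir: str | Path, config: SimulationConfig) -> None:
    """Write every generated table in the pipeline's on-disk formats.

    Produces mention TSV, per-source prediction TSVs, validated TSV,
    biotype TSV, Matrix Market matrix + features + barcodes + metadata,
    and the ground-truth JSON.
    """
    from . import sc_core  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.mentions.to_csv(outdir / "mentions.tsv", sep="\t", index=False)
    bt = pd.DataFrame(
        sorted(config.biotype_map().items()), columns=["gene_symbol", "biotype"]
    )
    bt.to_csv(outdir / "biotypes.tsv", sep="\t", index=False)
    pred_dir = outdir / "predictions"
    pred_dir.mkdir(exist_ok=True)
    for source, grp in result.predictions.groupby("source"):
        grp[["mirna", "target", "score"]].to_csv(
            pred_dir / f"{source}.tsv", sep="\t", index=False
        )
    result.validated.to_csv(outdir / "validated.tsv", sep="\t", index=False)
    sc_core.write_dataset(result.dataset, outdir / "matrix")
    result.truth.to_json(outdir / "ground_truth.json")


def config_from_yaml(path: str | Path) -> SimulationConfig:
    """Load a SimulationConfig from a YAML mapping of field overrides."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "planted_specific_pairs" in raw:
        raw["planted_specific_pairs"] = [tuple(p) for p in raw["planted_specific_pairs"]]
    if "planted_de" in raw:
        raw["planted_de"] = [tuple(p) for p in raw["planted_de"]]
    return SimulationConfig(**raw)
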