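"""Directed predictor->gene networks and their hub/exclusivity structure.

Each phenotype's fitted models define a bipartite directed graph with one
edge per nonzero coefficient (predictors are sources, modelled genes are
targets).  This module computes degree statistics, predictor sharing and
cross-phenotype exclusivity, miRNA hub identification with coefficient
distribution tests, and hub-knockout connectivity including a greedy
estimate of the minimal predictor set covering all genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import DataError
from .fitting import GeneModel
from .io import logger
from .stats import ks_two_sample


@dataclass
class PredictorNetwork:
    phenotype: str
    edges: pd.DataFrame  # columns: source, target, coefficient, omic
    outdegree: dict[str, int] = field(default_factory=dict)
    indegree: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = ["source", "target", "coefficient", "omic"]
        missing = set(cols) - set(self.edges.columns)
        if missing:
            raise DataError(f"edge frame missing columns {sorted(missing)}")
        self.edges = self.edges.loc[:, cols].reset_index(drop=True)
        if not self.outdegree:
            self.outdegree = self.edges["source"].value_counts().to_dict()
        if not self.indegree:
            self.indegree = self.edges["target"].value_counts().to_dict()

    @property
    def predictors(self) -> set[str]:
        return set(self.edges["source"])

    @property
    def genes(self) -> set[str]:
        return set(self.edges["target"])

    def genes_of(self, predictor: str) -> set[str]:
        hit = self.edges["source"] == predictor
        return set(self.edges.loc[hit, "target"])

    def to_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from((n, {"kind": "predictor"}) for n in self.predictors)
        g.add_nodes_from((n, {"kind": "gene"}) for n in self.genes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.source, row.target, coefficient=row.coefficient, omic=row.omic)
        return g


def build_network(models: Sequence[GeneModel], phenotype: str) -> PredictorNetwork:
    """One edge per nonzero coefficient of the phenotype's models."""
    rows = []
    omic_lookup: dict[str, str] = {}
    for m in models:
        if m.phenotype != phenotype:
            continue
        for omic, feats in m.selected_by_omic.items():
            for f in feats:
                omic_lookup[f] = omic
        for fid, beta in m.coef.items():
            rows.append((fid, m.gene, beta, omic_lookup[fid]))
    edges = pd.DataFrame(rows, columns=["source", "target", "coefficient", "omic"])
    return PredictorNetwork(phenotype=phenotype, edges=edges)


def network_from_edge_frame(frame: pd.DataFrame, phenotype: str | None = None) -> PredictorNetwork:
    """Rebuild a network from a (possibly multi-phenotype) edge-list frame."""
    if phenotype is not None and "phenotype" in frame.columns:
        frame = frame[frame["phenotype"] == phenotype]
        if frame.empty:
            raise DataError(f"no edges for phenotype {phenotype!r}")
    elif phenotype is None:
        phenos = set(frame.get("phenotype", []))
        if len(phenos) > 1:
            raise DataError("edge frame spans multiple phenotypes; pass one explicitly")
        phenotype = next(iter(phenos), "")
    return PredictorNetwork(phenotype=str(phenotype), edges=frame)


# ---------------------------------------------------------------------------
# sharing / exclusivity
# ---------------------------------------------------------------------------


@dataclass
class SharingSummary:
    """Exclusivity fractions and cross-phenotype coverage of associations."""

    exclusive_fraction: dict[str, float]  # per omic: predictors of exactly 1 gene
    association_phenotypes: dict[tuple[str, str], set[str]]  # (gene, predictor) -> phenotypes
    universal: dict[str, set[str]]  # gene -> predictors selected in all tumor phenotypes
    tumor_phenotypes: list[str]


def sharing_stats(
    networks: Sequence[PredictorNetwork], normal_phenotype: str = "Normal"
) -> SharingSummary:
    """Predictor exclusivity and cross-phenotype selection summary.

    Exclusivity counts a predictor as exclusive when, pooling edges over all
    supplied networks, it is selected for exactly one distinct gene.
    ``universal`` holds, per gene, the predictors selected for that gene in
    every tumor (non-normal) phenotype.
    """
    genes_by_predictor: dict[str, set[str]] = {}
    omic_of: dict[str, str] = {}
    association_phenotypes: dict[tuple[str, str], set[str]] = {}
    for net in networks:
        for row in net.edges.itertuples(index=False):
            genes_by_predictor.setdefault(row.source, set()).add(row.target)
            omic_of[row.source] = row.omic
            association_phenotypes.setdefault((row.target, row.source), set()).add(net.phenotype)

    exclusive_fraction: dict[str, float] = {}
    for omic in sorted(set(omic_of.values())):
        preds = [p for p, o in omic_of.items() if o == omic]
        if preds:
            n_excl = sum(1 for p in preds if len(genes_by_predictor[p]) == 1)
            exclusive_fraction[omic] = n_excl / len(preds)

    tumor = sorted({n.phenotype for n in networks} - {normal_phenotype})
    universal: dict[str, set[str]] = {}
    for (gene, pred), phenos in association_phenotypes.items():
        if tumor and set(tumor) <= phenos:
            universal.setdefault(gene, set()).add(pred)
    return SharingSummary(
        exclusive_fraction=exclusive_fraction,
        association_phenotypes=association_phenotypes,
        universal=universal,
        tumor_phenotypes=tumor,
    )


def sharing_frame(summary: SharingSummary) -> pd.DataFrame:
    rows = [
        {"gene": g, "predictor": p, "phenotypes": ",".join(sorted(phs))}
        for (g, p), phs in sorted(summary.association_phenotypes.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "predictor", "phenotypes"])


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------


@dataclass
class HubReport:
    phenotype: str
    hub: str
    outdegree: int
    ranking: list[tuple[str, int]]  # class predictors by descending outdegree
    ks_statistic: float
    ks_pvalue: float


def hub_analysis(
    networks: Sequence[PredictorNetwork],
    hub_class: str | None = "mirna",
    method: str = "asymp",
) -> list[HubReport]:
    """Rank predictors by outdegree per phenotype and test the top hub.

    By default the ranking is restricted to the miRNA class
    (``hub_class=None`` ranks all predictors).  The hub's coefficient values
    are compared with the pooled coefficients of all other same-class
    predictors by a two-sample KS test.
    """
    reports: list[HubReport] = []
    for net in networks:
        edges = net.edges
        if hub_class is not None:
            edges = edges[edges["omic"] == hub_class]
        if edges.empty:
            logger.warning("phenotype %s: no %s edges; hub analysis skipped", net.phenotype, hub_class)
            continue
        counts = edges["source"].value_counts()
        ranking = sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
        hub = ranking[0][0]
        hub_coefs = edges.loc[edges["source"] == hub, "coefficient"].to_numpy()
        rest = edges.loc[edges["source"] != hub, "coefficient"].to_numpy()
        if len(rest) >= 1 and len(hub_coefs) >= 1:
            d, p = ks_two_sample(hub_coefs, rest, method=method)
        else:
            d, p = float("nan"), float("nan")
        reports.append(
            HubReport(
                phenotype=net.phenotype,
                hub=hub,
                outdegree=int(ranking[0][1]),
                ranking=[(f, int(c)) for f, c in ranking],
                ks_statistic=d,
                ks_pvalue=p,
            )
        )
    return reports


# ---------------------------------------------------------------------------
# knockout / connectivity
# ---------------------------------------------------------------------------


@dataclass
class KnockoutResult:
    removed: list[str]
    component_sizes: list[int]  # undirected bipartite components, descending
    bridging_set: list[str] | None  # greedy cover; None when undefined
    uncovered_genes: set[str]

    @property
    def bridging_set_size(self) -> int | None:
        return None if self.bridging_set is None else len(self.bridging_set)


def greedy_cover(gene_sets: Mapping[str, set[str]], universe: set[str]) -> tuple[list[str], set[str]]:
    """Greedy set cover: largest remaining coverage first, ties lexicographic.

    Returns the chosen predictor list and any uncoverable genes.
    """
    uncovered = set(universe)
    chosen: list[str] = []
    coverable = set().union(*gene_sets.values()) if gene_sets else set()
    impossible = uncovered - coverable
    uncovered -= impossible
    while uncovered:
        best = min(
            gene_sets,
            key=lambda p: (-len(gene_sets[p] & uncovered), p),
        )
        gain = gene_sets[best] & uncovered
        if not gain:
            break
        chosen.append(best)
        uncovered -= gain
    return chosen, impossible


def knockout_connectivity(
    network: PredictorNetwork, remove: Iterable[str] = ()
) -> KnockoutResult:
    """Remove predictor nodes and summarize the surviving connectivity.

    Component sizes refer to the undirected projection of the bipartite
    graph.  The bridging set is a greedy estimate of the smallest predictor
    collection whose selected-gene sets cover every gene still present.
    Removing an absent node logs a warning and is otherwise a no-op.
    """
    remove = list(remove)
    present = network.predictors
    for node in remove:
        if node not in present:
            logger.warning("knockout: %r not a predictor in phenotype %s", node, network.phenotype)
    removed = [n for n in remove if n in present]
    edges = network.edges[~network.edges["source"].isin(removed)]
    genes = network.genes  # genes remain nodes even if isolated
    if edges.empty and not genes:
        return KnockoutResult(removed=removed, component_sizes=[], bridging_set=None, uncovered_genes=set())
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for row in edges.itertuples(index=False):
        graph.add_edge(row.source, row.target)
    sizes = sorted((len(c) for c in nx.connected_components(graph)), reverse=True)
    gene_sets: dict[str, set[str]] = {}
    for row in edges.itertuples(index=False):
        gene_sets.setdefault(row.source, set()).add(row.target)
    if not gene_sets:
        logger.warning("knockout left no predictors; cover undefined")
        return KnockoutResult(removed=removed, component_sizes=sizes, bridging_set=None, uncovered_genes=set(genes))
    cover, impossible = greedy_cover(gene_sets, set(genes))
    return KnockoutResult(
        removed=removed,
        component_sizes=sizes,
        bridging_set=cover,
        uncovered_genes=impossible,
    )
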