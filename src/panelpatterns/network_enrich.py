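"""Differential PPI-subnetwork extraction and term enrichment.

From one or more undirected gene–gene edge lists a merged interaction
network is built (duplicate edges collapsed, per-edge provenance kept).
Genes harbouring at least one variant significant in the allele-frequency
screen seed a group-specific subnetwork comprising the mapped seeds plus
their 1-hop neighbours and all induced edges. Pairs of subnetworks are
differenced to obtain group-unique gene sets, which are scored for term
over-representation with the hypergeometric upper-tail test and BH
correction over the tested terms.

The enrichment background defaults to every gene carrying at least one
term in the supplied annotation table: subnetwork members include 1-hop
neighbours from the full interactome, so a panel-restricted background
would be degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .popgen_stats import AFTestResult, benjamini_hochberg

logger = logging.getLogger(__name__)

__all__ = [
    "Subnetwork",
    "EnrichmentResult",
    "merge_networks",
    "read_edge_list",
    "read_annotation",
    "significant_genes",
    "group_subnetwork",
    "differential_genes",
    "hubs",
    "enrich",
    "pairwise_enrichment_contrast",
]


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (gene, gene) TSV edge list; extra columns ignored."""
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: edge line needs two genes, got {line!r}")
            edges.append((parts[0], parts[1]))
    return edges


def merge_networks(
    edge_lists: Mapping[str, Iterable[tuple[str, str]]] | Sequence[str | Path],
) -> nx.Graph:
    """Union of interaction edge lists into one undirected network.

    ``edge_lists`` is either a mapping ``source name → iterable of gene
    pairs`` or a sequence of TSV paths (source name = file stem). Gene
    symbols are upper-cased; self-loops are dropped (count logged);
    duplicate edges collapse with their provenance sets unioned (edge
    attribute ``sources``).
    """
    if not isinstance(edge_lists, Mapping):
        edge_lists = {Path(p).stem: read_edge_list(p) for p in edge_lists}
    G = nx.Graph()
    n_self = 0
    for source, edges in edge_lists.items():
        for a, b in edges:
            a, b = a.strip().upper(), b.strip().upper()
            if a == b:
                n_self += 1
                continue
            if G.has_edge(a, b):
                G.edges[a, b]["sources"].add(source)
            else:
                G.add_edge(a, b, sources={source})
    if n_self:
        logger.info("merge_networks: dropped %d self-loops", n_self)
    G.graph["self_loops_dropped"] = n_self
    if G.number_of_edges() == 0:
        raise ValueError("edge-list union is empty")
    return G


def significant_genes(
    results: Sequence[AFTestResult],
    variant_to_gene: Mapping[str, str],
    alpha: float = 0.05,
) -> set[str]:
    """Genes harbouring at least one variant with ``p_adj < alpha``.

    ``variant_to_gene`` maps variant labels (``chrom:pos:ref:alt``) or
    rsids to gene symbols. Unmappable significant variants are excluded
    with a logged count.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    genes: set[str] = set()
    n_unmapped = 0
    for r in results:
        if not r.p_adj < alpha:
            continue
        gene = variant_to_gene.get(r.variant.label)
        if gene is None and r.variant.rsid:
            gene = variant_to_gene.get(r.variant.rsid)
        if gene is None:
            n_unmapped += 1
            continue
        genes.add(gene.upper())
    if n_unmapped:
        logger.warning("significant_genes: %d significant variants had no "
                       "gene mapping and were excluded", n_unmapped)
    return genes


@dataclass
class Subnetwork:
    """Seed genes, their 1-hop neighbourhood, and the induced edges."""

    group: str
    seed_genes: set[str]
    member_genes: set[str]
    edges: set[tuple[str, str]]
    unmapped: list[str] = field(default_factory=list)

    def degree(self) -> dict[str, int]:
        deg = {g: 0 for g in self.member_genes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def write_edges(self, path: str | Path,
                    header_comments: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_comments:
                fh.write(f"#{line.lstrip('#')}\n")
            fh.write("#geneA\tgeneB\n")
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")


def group_subnetwork(network: nx.Graph, seeds: Iterable[str],
                     group: str = "") -> Subnetwork:
    """Induced subnetwork of the mapped seeds plus their 1-hop neighbours."""
    seeds = {s.upper() for s in seeds}
    mapped = {s for s in seeds if s in network}
    unmapped = sorted(seeds - mapped)
    members = set(mapped)
    for s in mapped:
        members.update(network.neighbors(s))
    edges = {tuple(sorted((a, b)))
             for a, b in network.subgraph(members).edges()}
    if unmapped:
        logger.info("group_subnetwork(%s): %d seeds not in network: %s",
                    group, len(unmapped), unmapped)
    return Subnetwork(group=group, seed_genes=seeds, member_genes=members,
                      edges=edges, unmapped=unmapped)


def differential_genes(sub_a: Subnetwork, sub_b: Subnetwork
                       ) -> tuple[set[str], set[str]]:
    """Member genes unique to each subnetwork of a pair."""
    return (sub_a.member_genes - sub_b.member_genes,
            sub_b.member_genes - sub_a.member_genes)


def hubs(sub: Subnetwork, k: int = 10) -> list[tuple[str, int]]:
    """Members ranked by within-subnetwork degree, ties by symbol."""
    if not sub.member_genes:
        raise ValueError("empty subnetwork has no hubs")
    deg = sub.degree()
    ranked = sorted(deg.items(), key=lambda it: (-it[1], it[0]))
    return ranked[: min(k, len(ranked))]


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one term in a query set."""

    term: str
    term_name: str
    k: int  # query genes carrying the term
    K: int  # background genes carrying the term
    n: int  # annotated query genes
    N: int  # background size
    p: float
    p_adj: float = float("nan")
    genes: tuple[str, ...] = ()


def enrich(
    query: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    background: Iterable[str] | None = None,
    term_names: Mapping[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Term over-representation in a gene set (hypergeometric upper tail).

    ``annotation`` maps gene symbol → iterable of term ids. The
    background defaults to all annotated genes; an explicit background
    is intersected with the annotated universe. Per term with at least
    one query gene, ``p = P(X ≥ k)`` for ``X ~ Hypergeom(N, K, n)``;
    BH correction runs across the tested terms only. Results are sorted
    by (p, term id).
    """
    ann = {g.upper(): {t for t in terms} for g, terms in annotation.items() if terms}
    if not ann:
        raise ValueError("empty annotation")
    universe = set(ann)
    if background is not None:
        universe &= {g.upper() for g in background}
        if not universe:
            raise ValueError("background contains no annotated genes")
    query_ann = {g.upper() for g in query} & universe
    if not query_ann:
        return []
    term_genes: dict[str, set[str]] = {}
    for g in universe:
        for t in ann[g]:
            term_genes.setdefault(t, set()).add(g)
    N, n = len(universe), len(query_ann)
    results = []
    for term in sorted(term_genes):
        overlap = term_genes[term] & query_ann
        if not overlap:
            continue  # untested: keeps the BH family to terms touched by the query
        K, k = len(term_genes[term]), len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(
            term=term, term_name=(term_names or {}).get(term, term),
            k=k, K=K, n=n, N=N, p=min(p, 1.0),
            genes=tuple(sorted(overlap))))
    adj = benjamini_hochberg([r.p for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
    results.sort(key=lambda r: (r.p, r.term))
    return results


def pairwise_enrichment_contrast(
    results_a: Sequence[EnrichmentResult],
    results_b: Sequence[EnrichmentResult],
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> list[EnrichmentResult]:
    """Terms significantly enriched in the first group but not the second.

    Significance is ``p < alpha`` on the raw p-value by default
    (``use_adjusted=True`` switches to ``p_adj``).
    """
    def sig(results: Sequence[EnrichmentResult]) -> set[str]:
        return {r.term for r in results
                if (r.p_adj if use_adjusted else r.p) < alpha}

    only_a = sig(results_a) - sig(results_b)
    return [r for r in results_a if r.term in only_a]


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame({
        "term": [r.term for r in results],
        "term_name": [r.term_name for r in results],
        "k": [r.k for r in results],
        "K": [r.K for r in results],
        "n": [r.n for r in results],
        "N": [r.N for r in results],
        "p": [r.p for r in results],
        "p_adj": [r.p_adj for r in results],
        "genes": [",".join(r.genes) for r in results],
    })


def read_annotation(path: str | Path
                    ) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read a ``gene  term_id  term_name`` TSV into lookup maps."""
    ann: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.lower().startswith("gene\t"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            gene, term = parts[0].upper(), parts[1]
            ann.setdefault(gene, set()).add(term)
            if len(parts) > 2 and parts[2]:
                names[term] = parts[2]
    if not ann:
        raise ValueError(f"{path}: no annotations")
    return ann, names
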