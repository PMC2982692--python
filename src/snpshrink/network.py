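"""Gene grouping by similarity threshold and SNP-network assembly.

Gene pairs whose functional similarity is strictly greater than a chosen
threshold are linked; connected components with at least two genes form
the gene groups.  SNPs located in grouped genes are then tested for
pairwise interaction against every SNP selected by the shrunken-centroid
stage, and pairs significant at P < 0.01 (by default) become edges of the
SNP network; its connected components of two or more SNPs are the reported
networks.  Graphs export to SIF, GraphML or an edge TSV for viewers such
as Cytoscape.
"""

from __future__ import annotations

import dataclasses
import warnings

import networkx as nx

from . import epistasis
from .io import GenotypeMatrix


@dataclasses.dataclass
class GeneGroupSet:
    """Gene pairs above a similarity threshold and their components."""

    threshold: float
    pairs: list                 # (gene1, gene2, sim), sim > threshold strictly
    groups: list                # connected components with >= 2 genes
    snp_map: dict               # gene -> list of SNP ids in that gene

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def grouped_snps(self) -> list:
        """SNP ids located in any grouped gene, in stable order."""
        out, seen = [], set()
        for grp in self.groups:
            for gene in sorted(grp):
                for sid in self.snp_map.get(gene, ()):
                    if sid not in seen:
                        seen.add(sid)
                        out.append(sid)
        return out

    def to_graph(self) -> nx.Graph:
        gr = nx.Graph()
        for g1, g2, s in self.pairs:
            gr.add_edge(g1, g2, sim=float(s))
        return gr


def group_genes(sim, threshold: float, snp_map: dict | None = None) -> GeneGroupSet:
    """Threshold a gene-similarity matrix into groups.

    Keeps gene pairs with similarity strictly greater than ``threshold``;
    groups are connected components of size >= 2 of the resulting graph.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    pairs = sim.pairs_above(threshold)
    graph = nx.Graph()
    for g1, g2, s in pairs:
        graph.add_edge(g1, g2, sim=s)
    groups = [set(c) for c in nx.connected_components(graph) if len(c) >= 2]
    groups.sort(key=lambda c: sorted(c)[0])
    return GeneGroupSet(threshold=threshold, pairs=pairs, groups=groups,
                        snp_map=dict(snp_map or {}))


def threshold_sweep(sim, thresholds) -> list[tuple[float, int, int]]:
    """(threshold, n_pairs, n_groups) per threshold, for trend tables."""
    return [(float(t), group_genes(sim, t).n_pairs, group_genes(sim, t).n_groups)
            for t in thresholds]


@dataclasses.dataclass
class SnpNetwork:
    """SNP interaction graph at a P-value cutoff."""

    p_threshold: float
    edges: list                 # EpistasisResult, p < p_threshold
    nodes: list

    def to_graph(self) -> nx.Graph:
        gr = nx.Graph()
        gr.add_nodes_from(self.nodes)
        for r in self.edges:
            gr.add_edge(r.snp1, r.snp2, p=float(r.p), or_int=float(r.or_int),
                        chi2=float(r.chi2))
        return gr

    @property
    def components(self) -> list:
        """Connected components with >= 2 SNPs (the reported networks)."""
        gr = self.to_graph()
        comps = [set(c) for c in nx.connected_components(gr) if len(c) >= 2]
        comps.sort(key=lambda c: sorted(c)[0])
        return comps


def build_snp_networks(groups: GeneGroupSet, selected, g: GenotypeMatrix,
                       p_threshold: float = 0.01,
                       case_label=None) -> SnpNetwork:
    """Scan grouped-gene SNPs against all selected SNPs; keep p < cutoff.

    ``selected`` is the SNP-id list from the shrunken-centroid stage;
    SNPs of grouped genes must be a subset of it.
    """
    set_a = groups.grouped_snps()
    selected = list(selected)
    if not set(set_a) <= set(selected):
        raise ValueError("grouped-gene SNPs must be among the selected SNPs")
    if not set_a:
        warnings.warn("no SNPs in grouped genes; empty network")
        return SnpNetwork(p_threshold=p_threshold, edges=[], nodes=[])
    results = epistasis.pairwise_scan(g, set_a, selected, p_threshold,
                                      case_label=case_label)
    nodes = sorted({r.snp1 for r in results} | {r.snp2 for r in results})
    return SnpNetwork(p_threshold=p_threshold, edges=results, nodes=nodes)


def export_graph(obj, fmt: str, path) -> None:
    """Write a SnpNetwork or GeneGroupSet as SIF, GraphML or edge TSV.

    GraphML and TSV carry edge attributes losslessly; SIF is topology only.
    TSV edges are sorted by ascending p (SNP networks) or descending
    similarity (gene groups).
    """
    graph = obj.to_graph()
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        rel = "pp" if isinstance(obj, SnpNetwork) else "sim"
        with open(path, "w") as fh:
            for u, v in sorted(graph.edges()):
                fh.write(f"{u}\t{rel}\t{v}\n")
            for node in sorted(nx.isolates(graph)):
                fh.write(f"{node}\n")
    elif fmt in ("tsv", "edge-tsv"):
        with open(path, "w") as fh:
            if isinstance(obj, SnpNetwork):
                fh.write("snp1\tsnp2\tp\tor_int\tchi2\n")
                for r in sorted(obj.edges, key=lambda r: r.p):
                    fh.write(f"{r.snp1}\t{r.snp2}\t{r.p!r}\t{r.or_int!r}\t"
                             f"{r.chi2!r}\n")
            else:
                fh.write("gene1\tgene2\tsim\n")
                for g1, g2, s in sorted(obj.pairs, key=lambda t: -t[2]):
                    fh.write(f"{g1}\t{g2}\t{s!r}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_graphml(path) -> nx.Graph:
    """Read back a GraphML export (round-trip counterpart)."""
    return nx.read_graphml(path)
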