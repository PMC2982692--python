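"""Information-content semantic similarity between genes over an ontology.

Information content (IC) of a term t is -log p(t), where p(t) is the
probability that a random annotation in t's namespace falls in t or one of
its descendants.  The relevance (Rel) similarity of two terms weights the
Lin IC-ratio by how non-generic the best common ancestor is:

    sim(t1, t2) = max over common ancestors a of
                  (2 * IC(a) / (IC(t1) + IC(t2))) * (1 - p(a)).

A shared root gives 0 (1 - p(root) = 0); identical specific terms approach
1.  Gene-level similarity is the best-match average (BMA) over the two
genes' annotation sets, computed per namespace (molecular function and
biological process by default) and then combined.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path

import networkx as nx
import numpy as np

_RELATIONS = ("is_a", "part_of")
NAMESPACE_CODES = {"molecular_function": "MF", "biological_process": "BP",
                   "cellular_component": "CC"}


@dataclasses.dataclass
class OntologyIndex:
    """Term DAG with ancestor closure, annotation probabilities and IC."""

    parents: dict            # term -> set of parent terms (is_a/part_of)
    namespace: dict          # term -> "MF" | "BP" | "CC"
    ancestors: dict          # term -> frozenset of ancestors incl. self
    p: dict                  # term -> annotation probability in (0, 1]
    ic: dict                 # term -> -log p
    annotations: dict        # gene -> set of terms (direct)

    @property
    def terms(self) -> set:
        return set(self.parents)

    def gene_terms(self, gene, ns: str) -> list:
        """Direct annotations of ``gene`` in namespace ``ns`` with known IC."""
        return sorted(t for t in self.annotations.get(gene, ())
                      if self.namespace.get(t) == ns and t in self.ic)


def _load_obo(obo) -> nx.MultiDiGraph:
    import obonet

    return obonet.read_obo(obo) if isinstance(obo, (str, Path)) else obo


def _parent_edges(graph: nx.MultiDiGraph) -> dict:
    """Extract is_a / part_of parent sets from an obonet graph.

    obonet edges point child -> parent with the relation as the key.
    """
    parents: dict = {t: set() for t in graph.nodes}
    for child, parent, rel in graph.edges(keys=True):
        if rel in _RELATIONS:
            parents[child].add(parent)
    return parents


def build_index(obo, annotations, use_pseudo: bool = True) -> OntologyIndex:
    """Build an :class:`OntologyIndex` from an OBO file and a gene->term table.

    ``annotations`` is a mapping gene -> iterable of term ids, or a path to
    a 2-column (gene, term) TSV.  Annotation counts propagate to ancestors:
    p(t) = (annotations to t or any descendant) / (total annotations in
    t's namespace).  Terms with zero count get the smallest observed p in
    their namespace when ``use_pseudo`` is set, else are excluded from
    similarity (no IC).
    """
    graph = _load_obo(obo)
    parents = _parent_edges(graph)
    namespace = {}
    for t, data in graph.nodes(data=True):
        ns = data.get("namespace", "")
        namespace[t] = NAMESPACE_CODES.get(ns, ns or "?")
    sub = nx.DiGraph((c, p_) for c, ps in parents.items() for p_ in ps)
    sub.add_nodes_from(parents)
    if not nx.is_directed_acyclic_graph(sub):
        raise ValueError("ontology is cyclic over is_a/part_of")

    # child->parent edges: topological order lists children before their
    # ancestors, so build closures parent-first by walking it in reverse
    ancestors: dict = {}
    for t in reversed(list(nx.topological_sort(sub))):
        acc = {t}
        for p_ in parents.get(t, ()):
            acc |= ancestors[p_]
        ancestors[t] = frozenset(acc)

    if isinstance(annotations, (str, Path)):
        table = {}
        with open(annotations) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                gene, term = line.split()[:2]
                table.setdefault(gene, set()).add(term)
        annotations = table
    ann: dict = {}
    for gene, terms in annotations.items():
        kept = set()
        for t in terms:
            if t not in parents:
                warnings.warn(f"annotation term {t} (gene {gene}) not in "
                              "ontology; dropped")
                continue
            kept.add(t)
        if kept:
            ann[gene] = kept

    # each direct annotation increments its term and every ancestor
    counts: dict = {t: 0 for t in parents}
    ns_totals: dict = {}
    for gene, terms in ann.items():
        for t in terms:
            ns_totals[namespace[t]] = ns_totals.get(namespace[t], 0) + 1
            for a in ancestors[t]:
                counts[a] += 1

    p: dict = {}
    ic: dict = {}
    for t in parents:
        total = ns_totals.get(namespace[t], 0)
        if total and counts[t] > 0:
            p[t] = counts[t] / total
            ic[t] = -math.log(p[t])
    if use_pseudo:
        ns_min = {}
        for t, val in p.items():
            ns = namespace[t]
            ns_min[ns] = min(ns_min.get(ns, 1.0), val)
        for t in parents:
            if t not in p and namespace[t] in ns_min:
                p[t] = ns_min[namespace[t]]
                ic[t] = -math.log(p[t])
    return OntologyIndex(parents=parents, namespace=namespace,
                         ancestors=ancestors, p=p, ic=ic, annotations=ann)


def term_sim_rel(t1, t2, index: OntologyIndex) -> float:
    """Rel similarity of two same-namespace terms, in [0, 1]."""
    ns1, ns2 = index.namespace.get(t1), index.namespace.get(t2)
    if ns1 != ns2:
        raise ValueError(f"terms {t1} ({ns1}) and {t2} ({ns2}) are in "
                         "different namespaces")
    if t1 not in index.ic or t2 not in index.ic:
        raise KeyError("term without information content (not annotated "
                       "and pseudo-count off)")
    denom = index.ic[t1] + index.ic[t2]
    if denom == 0:
        return 0.0
    common = index.ancestors[t1] & index.ancestors[t2]
    best = 0.0
    for a in common:
        if a not in index.ic:
            continue
        score = (2.0 * index.ic[a] / denom) * (1.0 - index.p[a])
        best = max(best, score)
    return best


def _bma(terms1, terms2, index: OntologyIndex) -> float:
    """Best-match average of two term sets (both directions)."""
    sim = np.array([[term_sim_rel(a, b, index) for b in terms2]
                    for a in terms1])
    return float((sim.max(axis=1).mean() + sim.max(axis=0).mean()) / 2.0)


def gene_sim(g1, g2, index: OntologyIndex, namespaces=("MF", "BP"),
             combine: str = "mean") -> float | None:
    """Gene-level Rel/BMA similarity combined over namespaces.

    Per namespace where both genes carry annotations, compute the
    best-match average; combine with ``mean`` (default), ``max`` or
    ``min`` over namespaces.  Returns None when no namespace has both
    genes annotated.
    """
    scores = []
    for ns in namespaces:
        t1 = index.gene_terms(g1, ns)
        t2 = index.gene_terms(g2, ns)
        if t1 and t2:
            scores.append(_bma(t1, t2, index))
    if not scores:
        return None
    if combine == "mean":
        return float(np.mean(scores))
    if combine == "max":
        return float(np.max(scores))
    if combine == "min":
        return float(np.min(scores))
    raise ValueError(f"unknown combine rule {combine!r}")


@dataclasses.dataclass
class GeneSimilarityMatrix:
    """Symmetric gene x gene similarity in [0, 1].

    The diagonal is a gene's self-BMA, which is < 1 for generic
    annotations; it need not dominate off-diagonal entries.
    """

    genes: list
    sim: np.ndarray
    ontologies_used: tuple = ("MF", "BP")

    def pairs_above(self, threshold: float) -> list[tuple]:
        """(gene1, gene2, sim) for unordered pairs with sim strictly above
        the threshold."""
        out = []
        for i in range(len(self.genes)):
            for j in range(i + 1, len(self.genes)):
                if self.sim[i, j] > threshold:
                    out.append((self.genes[i], self.genes[j],
                                float(self.sim[i, j])))
        return out


def gene_similarity_matrix(genes, index: OntologyIndex,
                           namespaces=("MF", "BP"),
                           combine: str = "mean") -> GeneSimilarityMatrix:
    """All pairwise gene similarities; unannotated genes are excluded."""
    usable = [g for g in genes
              if any(index.gene_terms(g, ns) for ns in namespaces)]
    skipped = set(genes) - set(usable)
    if skipped:
        warnings.warn(f"genes without usable annotations excluded: "
                      f"{sorted(skipped)}")
    m = len(usable)
    sim = np.zeros((m, m))
    for i in range(m):
        for j in range(i, m):
            val = gene_sim(usable[i], usable[j], index, namespaces, combine)
            sim[i, j] = sim[j, i] = 0.0 if val is None else val
    return GeneSimilarityMatrix(genes=usable, sim=sim,
                                ontologies_used=tuple(namespaces))
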