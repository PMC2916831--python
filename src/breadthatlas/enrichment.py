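"""Hypergeometric over-representation tests on a term DAG.

Implements the classical upper-tail hypergeometric gene-set test and its
conditional variant: terms are processed leaves-to-root, and when a term is
tested, genes annotated to its already-significant direct children are removed
from both the term's gene set and the universe, so a parent is only reported
when there is evidence beyond that provided by its significant children.
Gene annotations obey the true-path rule: a gene annotated to a term is
implicitly annotated to all of the term's ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats

from .errors import FormatError, InputError

__all__ = [
    "TermDAG",
    "hypergeometric_test",
    "conditional_enrichment",
    "read_term_edges",
    "read_gene_annotations",
]


@dataclass
class TermDAG:
    """Term hierarchy (child -> parent edges) with propagated annotations.

    ``annotations`` maps term -> frozenset of genes after true-path
    propagation, so every annotated gene of a child is an annotated gene of
    each of its ancestors.
    """

    graph: nx.DiGraph
    annotations: dict[str, frozenset] = field(default_factory=dict)

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str]],
        gene_terms: list[tuple[str, str]],
    ) -> "TermDAG":
        """Build from (child, parent) term edges and (gene, term) annotations."""
        graph = nx.DiGraph()
        graph.add_edges_from(edges)
        for _, term in gene_terms:
            graph.add_node(term)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise InputError(f"term hierarchy contains a cycle: {cycle}")
        direct: dict[str, set] = {t: set() for t in graph.nodes}
        for gene, term in gene_terms:
            if term not in direct:
                raise InputError(f"annotation references unknown term {term!r}")
            direct[term].add(gene)
        # true-path propagation: ancestors are reachable along child->parent
        annotations = {}
        for term in graph.nodes:
            genes = set(direct[term])
            for desc in nx.ancestors(graph, term):  # terms that reach `term`
                genes |= direct[desc]
            annotations[term] = frozenset(genes)
        return cls(graph=graph, annotations=annotations)

    def children(self, term: str) -> list[str]:
        """Direct children (terms with an edge into ``term``)."""
        return list(self.graph.predecessors(term))

    def topological_terms(self) -> list[str]:
        """Terms ordered children-before-parents."""
        return list(nx.topological_sort(self.graph))

    def annotated_genes(self) -> frozenset:
        out: set = set()
        for genes in self.annotations.values():
            out |= genes
        return frozenset(out)


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``k`` query genes in the term, ``n`` query genes in the universe, ``K``
    universe genes in the term, ``N`` universe genes. Computed via the
    log-space survival function for numerical stability.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N):
        raise InputError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def conditional_enrichment(
    dag: TermDAG,
    query,
    universe,
    alpha: float = 0.01,
    conditional: bool = True,
    adjust_universe: bool = True,
) -> pd.DataFrame:
    """Term-by-term over-representation of ``query`` within ``universe``.

    Terms are visited leaves-to-root. With ``conditional=True``, genes
    annotated to a term's already-significant *direct* children are removed
    from the term's gene set — and, when ``adjust_universe`` (default), from
    the universe — before testing, so the reported p-value reflects evidence
    beyond the children. A term is significant when its (conditional) p-value
    is < ``alpha``. Returns a frame sorted by p-value with columns
    k, n, K, N, pvalue, significant, conditional.
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        raise InputError("query genes must be a subset of the universe")
    annotated = dag.annotated_genes()
    stray = universe - annotated
    if stray:
        raise InputError(
            f"{len(stray)} universe genes carry no term annotation "
            f"(e.g. {sorted(stray)[:3]})"
        )
    significant: dict[str, bool] = {}
    rows = []
    for term in dag.topological_terms():
        term_genes = dag.annotations[term] & universe
        removed: set = set()
        if conditional:
            for child in dag.children(term):
                if significant.get(child, False):
                    removed |= dag.annotations[child] & universe
        local_universe = universe - removed if adjust_universe else universe
        local_term = (term_genes - removed) & local_universe
        local_query = query & local_universe
        k = len(local_query & local_term)
        n = len(local_query)
        K = len(local_term)
        N = len(local_universe)
        p = 1.0 if (K == 0 or n == 0) else hypergeometric_test(k, n, K, N)
        significant[term] = p < alpha
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "pvalue": p,
                "significant": significant[term],
                "conditional": bool(conditional and removed),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    return out.sort_values(["pvalue", "term"], kind="mergesort")


def read_term_edges(path) -> list[tuple[str, str]]:
    """Read a child-parent term TSV (columns child, parent)."""
    df = pd.read_csv(path, sep="\t")
    if not {"child", "parent"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns ['child', 'parent']")
    return list(df[["child", "parent"]].itertuples(index=False, name=None))


def read_gene_annotations(path) -> list[tuple[str, str]]:
    """Read a gene-term annotation TSV (columns gene, term)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "term"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns ['gene', 'term']")
    return list(df[["gene", "term"]].itertuples(index=False, name=None))
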