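"""Module enrichment, semantic similarity and edge-overlap benchmarking.

Three validation tools for an inferred functional network:

* hypergeometric over-representation of gene-set collections in modules,
  with Benjamini-Hochberg adjustment within each collection;
* information-content (Lin) semantic similarity of gene pairs over an
  annotation DAG, aggregated by best-match average, used to compare edge
  sets via a Wilcoxon rank-sum test;
* simple edge-overlap counts against reference interaction networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "hypergeom_enrichment",
    "module_enrichment_table",
    "OntologyDAG",
    "term_information_content",
    "gene_pair_semantic_similarity",
    "compare_edge_similarity",
    "edge_overlap",
]


@dataclass
class EnrichmentResult:
    module_id: str
    set_id: str
    k: int  # overlap
    n: int  # module size (within universe)
    K: int  # gene-set size (within universe)
    N: int  # universe size
    p_value: float
    q_value: float = float("nan")


def hypergeom_enrichment(
    module: set[str],
    gene_set: set[str],
    universe: set[str],
    module_id: str = "module",
    set_id: str = "set",
) -> EnrichmentResult:
    """Exact upper-tail hypergeometric P(X >= k) for the module/set overlap."""
    if not universe:
        raise ValueError("empty universe")
    if not module <= universe or not gene_set <= universe:
        raise ValueError("module and gene set must be subsets of the universe")
    N, n, K = len(universe), len(module), len(gene_set)
    k = len(module & gene_set)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(module_id, set_id, k, n, K, N, min(p, 1.0))


def module_enrichment_table(
    modules: dict[str, set[str]],
    collections: dict[str, dict[str, set[str]]],
    universe: set[str],
) -> pd.DataFrame:
    """All module x set tests; BH-adjusted q-values within each collection."""
    rows = []
    for coll_name, sets in sorted(collections.items()):
        family: list[EnrichmentResult] = []
        for mod_id, members in sorted(modules.items()):
            for set_id, genes in sorted(sets.items()):
                family.append(
                    hypergeom_enrichment(
                        members & universe, genes & universe, universe,
                        module_id=mod_id, set_id=set_id,
                    )
                )
        if family:
            pvals = [r.p_value for r in family]
            _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
            for r, q in zip(family, qvals):
                r.q_value = float(q)
        rows.extend(
            {
                "collection": coll_name,
                "module": r.module_id,
                "set": r.set_id,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p": r.p_value,
                "q": r.q_value,
            }
            for r in family
        )
    return pd.DataFrame(
        rows, columns=["collection", "module", "set", "k", "n", "K", "N", "p", "q"]
    )


class OntologyDAG:
    """A rooted annotation DAG given as child -> parent edges."""

    def __init__(self, edges: pd.DataFrame, root: str | None = None):
        g = nx.DiGraph()
        for child, parent in edges[["child", "parent"]].itertuples(index=False):
            g.add_edge(str(child), str(parent))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if root is None:
            if len(roots) != 1:
                raise ValueError(f"expected a single root, found {roots}")
            root = roots[0]
        elif root not in g.nodes:
            g.add_node(root)
        self.graph = g
        self.root = root
        for t in g.nodes:
            if t != root and not nx.has_path(g, t, root):
                raise ValueError(f"term {t!r} cannot reach the root {root!r}")

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        """Term itself plus all its ancestors up to the root."""
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in ontology")
        return {term} | nx.descendants(self.graph, term)  # edges point child->parent


def term_information_content(
    ont: OntologyDAG, annotations: dict[str, set[str]]
) -> dict[str, float]:
    """IC(t) = -ln(n_t / n_root) after propagating annotations to ancestors."""
    gene_terms: dict[str, set[str]] = {}
    for gene, terms in annotations.items():
        propagated: set[str] = set()
        for t in terms:
            if t not in ont.terms:
                raise KeyError(f"annotated term {t!r} missing from the ontology DAG")
            propagated |= ont.ancestors(t)
        if propagated:
            gene_terms[gene] = propagated

    counts: dict[str, int] = {t: 0 for t in ont.terms}
    for terms in gene_terms.values():
        for t in terms:
            counts[t] += 1
    n_root = counts.get(ont.root, 0)
    ic: dict[str, float] = {}
    for t, c in counts.items():
        if c == 0 or n_root == 0:
            ic[t] = float("nan")  # unannotated term: IC undefined
        else:
            ic[t] = -log(c / n_root)
    ic[ont.root] = 0.0
    return ic


def _lin(t1: str, t2: str, ont: OntologyDAG, ic: dict[str, float]) -> float:
    common = ont.ancestors(t1) & ont.ancestors(t2)
    ic1, ic2 = ic.get(t1, float("nan")), ic.get(t2, float("nan"))
    if not common or not np.isfinite(ic1) or not np.isfinite(ic2):
        return 0.0
    mica = max((ic.get(t, 0.0) for t in common if np.isfinite(ic.get(t, float("nan")))), default=0.0)
    denom = ic1 + ic2
    return 2.0 * mica / denom if denom > 0 else 0.0


def gene_pair_semantic_similarity(
    gene_a: str,
    gene_b: str,
    ont: OntologyDAG,
    annotations: dict[str, set[str]],
    ic: dict[str, float] | None = None,
    method: str = "lin",
    combine: str = "bma",
) -> float:
    """Best-match-average Lin similarity of two genes' term sets.

    Unannotated genes (or genes whose only shared ancestor is the root)
    score 0 by policy.
    """
    if method != "lin" or combine != "bma":
        raise ValueError("only method='lin' with combine='bma' is implemented")
    if ic is None:
        ic = term_information_content(ont, annotations)
    terms_a = sorted(annotations.get(gene_a, set()) - {ont.root})
    terms_b = sorted(annotations.get(gene_b, set()) - {ont.root})
    if not terms_a or not terms_b:
        return 0.0
    sim = np.array([[_lin(ta, tb, ont, ic) for tb in terms_b] for ta in terms_a])
    return float((sim.max(axis=1).mean() + sim.max(axis=0).mean()) / 2.0)


def compare_edge_similarity(
    edges_a: set[frozenset[str]],
    edges_b: set[frozenset[str]],
    ont: OntologyDAG,
    annotations: dict[str, set[str]],
) -> tuple[float, float, float]:
    """Mean per-edge semantic similarity of two edge sets + rank-sum p-value.

    The test is the two-sided Wilcoxon rank-sum with normal approximation
    and tie correction (Mann-Whitney U, asymptotic method).
    """
    if not edges_a or not edges_b:
        raise ValueError("both edge sets must be non-empty")
    ic = term_information_content(ont, annotations)

    def sims(edges: set[frozenset[str]]) -> np.ndarray:
        vals = []
        for e in sorted(edges, key=sorted):
            a, b = sorted(e)
            vals.append(
                gene_pair_semantic_similarity(a, b, ont, annotations, ic=ic)
            )
        return np.array(vals)

    sa, sb = sims(edges_a), sims(edges_b)
    if np.ptp(np.concatenate([sa, sb])) == 0:
        p = 1.0  # all values tied: no evidence of a shift
    else:
        p = float(
            mannwhitneyu(
                sa, sb, alternative="two-sided", method="asymptotic",
                use_continuity=False,
            ).pvalue
        )
    return float(sa.mean()), float(sb.mean()), p


def edge_overlap(
    edges_a: set[frozenset[str]],
    references: dict[str, set[frozenset[str]]],
) -> dict:
    """Counts of A-edges found in each reference, and in none of them.

    Percentages are relative to |A|.
    """
    n_a = len(edges_a)
    out: dict = {"n_edges": n_a, "references": {}, }
    seen: set[frozenset[str]] = set()
    for name, ref in sorted(references.items()):
        inter = edges_a & ref
        seen |= inter
        out["references"][name] = {
            "overlap": len(inter),
            "percent": 100.0 * len(inter) / n_a if n_a else 0.0,
        }
    unique = n_a - len(seen)
    out["unique"] = unique
    out["unique_percent"] = 100.0 * unique / n_a if n_a else 0.0
    return out
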