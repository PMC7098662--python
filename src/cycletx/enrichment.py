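"""Term over-representation tests for gene clusters.

Annotations are first propagated up the ontology (true-path rule: a gene
annotated to a term is annotated to all its ancestors).  Two modes:

* term-for-term — the standard one-sided hypergeometric test of the study
  set against the population;
* parent-child-union — the population for term t is restricted to genes
  annotated to the union of t's parents, so a term is only called enriched
  when it carries signal beyond what its parents already explain.

Bonferroni correction counts only the terms actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger("cycletx.enrichment")

__all__ = ["AnnotationMap", "term_for_term", "parent_child_union"]


@dataclass
class AnnotationMap:
    """Gene -> term annotations over a DAG of terms (edges child -> parent).

    Annotation propagation to ancestors happens at construction.
    """

    gene_to_terms: dict[str, set[str]]
    ontology: nx.DiGraph = field(default_factory=nx.DiGraph)

    def __post_init__(self) -> None:
        if self.ontology.number_of_nodes() and not nx.is_directed_acyclic_graph(self.ontology):
            raise ValueError("ontology graph must be acyclic")
        propagated = {}
        for gene, terms in self.gene_to_terms.items():
            closed = set(terms)
            for t in terms:
                if t in self.ontology:
                    closed |= nx.descendants(self.ontology, t)  # ancestors: child->parent edges
            propagated[gene] = closed
        self.gene_to_terms = propagated
        self._term_to_genes: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                self._term_to_genes.setdefault(t, set()).add(gene)

    def genes_with(self, term: str) -> set[str]:
        return self._term_to_genes.get(term, set())

    @property
    def terms(self) -> list[str]:
        return sorted(self._term_to_genes)

    def parents(self, term: str) -> set[str]:
        if term not in self.ontology:
            return set()
        return set(self.ontology.successors(term))


def _finish(rows: list[dict], alpha: float) -> pd.DataFrame:
    out = pd.DataFrame(rows)
    if out.empty:
        return pd.DataFrame(columns=["term", "study_count", "study_n", "population_count",
                                     "population_n", "p", "p_bonferroni", "significant"])
    m = len(out)
    out["p_bonferroni"] = (out["p"] * m).clip(upper=1.0)
    out["significant"] = out["p_bonferroni"] < alpha
    out.attrs["n_tests"] = m
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def term_for_term(study: set[str], population: set[str], ann: AnnotationMap,
                  alpha: float = 0.05) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of every term annotating
    at least one population gene."""
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    n_pop, n_study = len(population), len(study)
    rows = []
    for term in ann.terms:
        pop_k = len(ann.genes_with(term) & population)
        if pop_k == 0:
            continue
        study_k = len(ann.genes_with(term) & study)
        p = float(hypergeom.sf(study_k - 1, n_pop, pop_k, n_study))
        rows.append({"term": term, "study_count": study_k, "study_n": n_study,
                     "population_count": pop_k, "population_n": n_pop, "p": p})
    return _finish(rows, alpha)


def parent_child_union(study: set[str], population: set[str], ann: AnnotationMap,
                       alpha: float = 0.05) -> pd.DataFrame:
    """Parent-conditioned over-representation.

    For term t, both study and population are restricted to genes annotated
    to the union of t's parents; the hypergeometric test then asks whether
    the study holds more t-annotated genes than expected within that
    conditioned background.  Terms with no parent (roots) are not tested.
    """
    if not study <= population:
        raise ValueError("study set must be a subset of the population")
    rows = []
    skipped_roots = 0
    for term in ann.terms:
        parents = ann.parents(term)
        if not parents:
            skipped_roots += 1
            continue
        parent_pool = set().union(*(ann.genes_with(p) for p in parents))
        pop_cond = parent_pool & population
        study_cond = parent_pool & study
        term_genes = ann.genes_with(term)
        pop_k = len(term_genes & pop_cond)
        if pop_k == 0 or not pop_cond:
            continue
        study_k = len(term_genes & study_cond)
        p = float(hypergeom.sf(study_k - 1, len(pop_cond), pop_k, len(study_cond)))
        rows.append({"term": term, "study_count": study_k, "study_n": len(study_cond),
                     "population_count": pop_k, "population_n": len(pop_cond), "p": p})
    if skipped_roots:
        logger.info("parent_child_union: %d root terms not tested", skipped_roots)
    return _finish(rows, alpha)
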