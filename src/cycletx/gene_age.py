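"""Gene ages by Dollo parsimony on a rooted species tree.

Under a Dollo model (one gain, unlimited losses) the most parsimonious
origin of a gene family is the most recent common ancestor of the species
that possess it; any earlier placement only adds losses.  Each origin node
maps to an integer age class of the focal species — ages 0 ("species-
specific") through 5 ("Paneukaryotic") in the default scheme — and clusters
of genes are tested for age enrichment against a background with two-sided
Fisher tests and Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

logger = logging.getLogger("cycletx.gene_age")

__all__ = [
    "SpeciesTree",
    "DolloAgeMap",
    "dollo_origin",
    "assign_ages",
    "fisher_two_sided",
    "age_enrichment",
    "age_enrichment_table",
    "DEFAULT_AGE_LABELS",
]


def fisher_two_sided(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]];
    returns (odds ratio, p)."""
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)

DEFAULT_AGE_LABELS = {
    0: "species-specific",
    1: "Filozoa",
    2: "Holozoa",
    3: "Opisthokonta",
    4: "Unikonta",
    5: "Paneukaryotic",
}


@dataclass
class SpeciesTree:
    """A rooted species tree with labeled internal nodes and a focal leaf."""

    tree: dendropy.Tree
    focal_species: str

    @classmethod
    def from_newick(cls, newick: str, focal_species: str) -> "SpeciesTree":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        tree.is_rooted = True
        obj = cls(tree=tree, focal_species=focal_species)
        obj.find_node(focal_species)  # validate
        return obj

    @property
    def leaf_labels(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def find_node(self, label: str) -> dendropy.Node:
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                if node.taxon is not None and node.taxon.label == label:
                    return node
            elif node.label == label:
                return node
        raise ValueError(f"node {label!r} not in tree")

    @staticmethod
    def node_label(node: dendropy.Node) -> str:
        return node.taxon.label if node.is_leaf() else (node.label or "")

    def mrca(self, leaf_labels: set[str]) -> dendropy.Node:
        missing = sorted(leaf_labels - self.leaf_labels)
        if missing:
            raise ValueError(f"species not in tree: {missing}")
        if len(leaf_labels) == 1:
            return self.find_node(next(iter(leaf_labels)))
        return self.tree.mrca(taxon_labels=list(leaf_labels))

    def ancestor_labels(self, leaf_label: str) -> list[str]:
        """Labels along the path focal leaf -> root (inclusive)."""
        node = self.find_node(leaf_label)
        out = []
        while node is not None:
            out.append(self.node_label(node))
            node = node.parent_node
        return out


@dataclass
class DolloAgeMap:
    """Origin node and integer age class per orthogroup, propagated to genes."""

    orthogroup_origin: dict[str, str] = field(default_factory=dict)
    orthogroup_age: dict[str, int] = field(default_factory=dict)
    gene_age: dict[str, int] = field(default_factory=dict)
    age_labels: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_AGE_LABELS))

    def age_of(self, gene: str) -> int:
        # genes in no orthogroup default to the youngest class
        return self.gene_age.get(gene, 0)

    def distribution(self, genes) -> pd.Series:
        ages = pd.Series([self.age_of(g) for g in genes], dtype=int)
        return ages.value_counts().sort_index()


def dollo_origin(presence: set[str], tree: SpeciesTree) -> dendropy.Node:
    """Most parsimonious single-gain origin = MRCA of the presence set."""
    if not presence:
        raise ValueError("presence set is empty")
    return tree.mrca(set(presence))


def assign_ages(
    universe: "OrthogroupUniverse",
    tree: SpeciesTree,
    node_age_map: dict[str, int],
    age_labels: dict[int, str] | None = None,
) -> DolloAgeMap:
    """Dollo age per orthogroup containing the focal species, propagated to
    its focal genes.  ``node_age_map`` maps node labels (ancestors of the
    focal leaf, plus the leaf itself) to integer age classes."""
    out = DolloAgeMap(age_labels=dict(age_labels or DEFAULT_AGE_LABELS))
    focal = tree.focal_species
    skipped = 0
    for og in universe.orthogroup_ids:
        per_species = universe.members[og]
        focal_genes = per_species.get(focal, [])
        if not focal_genes:
            skipped += 1
            continue
        presence = {sp for sp, genes in per_species.items() if genes}
        node = dollo_origin(presence, tree)
        label = SpeciesTree.node_label(node)
        if label not in node_age_map:
            raise ValueError(f"origin node {label!r} has no age class assigned")
        age = node_age_map[label]
        out.orthogroup_origin[og] = label
        out.orthogroup_age[og] = age
        for g in focal_genes:
            out.gene_age[g] = age
    if skipped:
        logger.info("assign_ages: skipped %d orthogroups without a focal-species member",
                    skipped)
    return out


def age_enrichment(
    cluster_genes: set[str],
    background: set[str],
    ages: DolloAgeMap,
    n_tests: int | None = None,
    age_classes: list[int] | None = None,
) -> pd.DataFrame:
    """Two-sided Fisher tests of each age class, cluster vs rest of background.

    The 2x2 table per age is (in-cluster vs not) x (this age vs other).
    ``n_tests`` sets the Bonferroni family size (defaults to the number of
    ages tested in this call; a pipeline testing several clusters passes
    clusters x ages).
    """
    if not cluster_genes:
        raise ValueError("empty cluster")
    if not cluster_genes <= background:
        raise ValueError("cluster must be a subset of the background universe")
    rest = background - cluster_genes
    cl_ages = np.array([ages.age_of(g) for g in cluster_genes])
    bg_ages = np.array([ages.age_of(g) for g in rest])
    classes = age_classes if age_classes is not None else sorted(ages.age_labels)
    m = n_tests if n_tests is not None else len(classes)
    rows = []
    for age in classes:
        a = int((cl_ages == age).sum())
        b = cl_ages.size - a
        c = int((bg_ages == age).sum())
        d = bg_ages.size - c
        _, p = fisher_two_sided(a, b, c, d)
        frac_bg = (a + c) / (len(background))
        ratio = (a / cl_ages.size) / frac_bg if frac_bg > 0 else np.nan
        rows.append({
            "age": age,
            "age_label": ages.age_labels.get(age, str(age)),
            "cluster_count": a,
            "cluster_other": b,
            "background_count": c,
            "background_other": d,
            "enrichment_ratio": ratio,
            "direction": "enriched" if (ratio is not np.nan and ratio > 1) else "depleted",
            "p": p,
            "p_bonferroni": min(1.0, p * m),
        })
    return pd.DataFrame(rows)


def age_enrichment_table(
    clusters: dict[str, set[str]],
    background: set[str],
    ages: DolloAgeMap,
) -> pd.DataFrame:
    """Age enrichment for several clusters with one Bonferroni family over
    all cluster x age cells."""
    classes = sorted(ages.age_labels)
    m = len(clusters) * len(classes)
    parts = []
    for name, genes in clusters.items():
        tab = age_enrichment(genes, background, ages, n_tests=m, age_classes=classes)
        tab.insert(0, "cluster", name)
        parts.append(tab)
    return pd.concat(parts, ignore_index=True)
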