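"""Dollo-parsimony ages: oracle equivalence of the MRCA origin, gene-level
propagation, and Fisher age-enrichment arithmetic."""

import math
from fractions import Fraction

import numpy as np
import pytest

from cycletx import DolloAgeMap, OrthogroupUniverse, assign_ages, dollo_origin
from cycletx.gene_age import SpeciesTree, age_enrichment, age_enrichment_table, fisher_two_sided
from cycletx.simulate import generate_family_history


# ---------------------------------------------------------------------------
# brute-force Dollo oracle: try every single-gain placement, count losses
# ---------------------------------------------------------------------------

def brute_force_origin(presence: set, tree: SpeciesTree):
    """Minimal-loss single-gain placement, enumerated over every node."""
    def leaves_under(node):
        return {l.taxon.label for l in node.leaf_iter()}

    def losses(node):
        # number of pruned maximal subtrees without any present leaf
        if node.is_leaf():
            return 0 if node.taxon.label in presence else None
        count = 0
        for child in node.child_nodes():
            sub = leaves_under(child)
            if sub & presence:
                count += losses(child)
            else:
                count += 1
        return count

    best, best_cost = None, None
    for node in tree.tree.preorder_node_iter():
        if presence <= leaves_under(node):
            cost = losses(node)
            if best_cost is None or cost < best_cost:
                best, best_cost = node, cost
    return best


def random_binary_tree(n_leaves: int, rng) -> SpeciesTree:
    names = [f"L{i}" for i in range(n_leaves)]
    nodes = [f"{n}" for n in names]
    counter = [0]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        label = f"N{counter[0]}"
        counter[0] += 1
        merged = f"({nodes[i]},{nodes[j]}){label}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return SpeciesTree.from_newick(nodes[0] + ";", focal_species="L0")


class TestDolloOrigin:
    def test_all_leaves_gives_root(self, species_tree):
        node = dollo_origin(species_tree.leaf_labels, species_tree)
        assert SpeciesTree.node_label(node) == "Paneukaryotic"

    def test_focal_only_gives_leaf(self, species_tree):
        node = dollo_origin({"Cowc"}, species_tree)
        assert node.is_leaf()

    def test_distant_pair_gives_root_matching_brute_force(self, species_tree):
        presence = {"Cowc", "Atha"}
        node = dollo_origin(presence, species_tree)
        oracle = brute_force_origin(presence, species_tree)
        assert node is oracle
        assert SpeciesTree.node_label(node) == "Paneukaryotic"

    def test_unknown_species_named_in_error(self, species_tree):
        with pytest.raises(ValueError, match="Xenoturbella"):
            dollo_origin({"Cowc", "Xenoturbella"}, species_tree)

    def test_empty_presence_rejected(self, species_tree):
        with pytest.raises(ValueError):
            dollo_origin(set(), species_tree)

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            tree = random_binary_tree(8, rng)
            leaves = sorted(tree.leaf_labels)
            size = rng.integers(1, len(leaves) + 1)
            presence = set(rng.choice(leaves, size=size, replace=False)) | {"L0"}
            assert dollo_origin(presence, tree) is brute_force_origin(presence, tree)

    def test_invariant_origin_depends_only_on_mrca(self, species_tree):
        # removing presence leaves inside the MRCA clade (keeping the MRCA
        # fixed) does not move the origin
        full = {"Cowc", "Mvib", "Mbre", "Scer"}
        reduced = {"Cowc", "Scer"}
        assert dollo_origin(full, species_tree) is dollo_origin(reduced, species_tree)

    def test_age_monotone_in_presence(self, species_tree, node_ages):
        chain = [{"Cowc"}, {"Cowc", "Mvib"}, {"Cowc", "Mbre"},
                 {"Cowc", "Scer"}, {"Cowc", "Ddis"}, {"Cowc", "Atha"}]
        ages = [node_ages[SpeciesTree.node_label(dollo_origin(p, species_tree))]
                for p in chain]
        assert ages == sorted(ages)


class TestAssignAges:
    def _universe(self):
        return OrthogroupUniverse({
            "OG1": {"Cowc": ["c1", "c2"], "Atha": ["a1"]},       # pan-eukaryotic
            "OG2": {"Cowc": ["c3"], "Mvib": ["m1"]},             # Filozoa
            "OG3": {"Mbre": ["b1"], "Scer": ["s1"]},             # no focal member
        })

    def test_gene_level_propagation(self, species_tree, node_ages):
        ages = assign_ages(self._universe(), species_tree, node_ages)
        assert ages.gene_age["c1"] == ages.gene_age["c2"] == 5
        assert ages.gene_age["c3"] == 1
        assert "OG3" not in ages.orthogroup_origin

    def test_unassigned_gene_defaults_to_zero(self, species_tree, node_ages):
        ages = assign_ages(self._universe(), species_tree, node_ages)
        assert ages.age_of("orphan_gene") == 0

    def test_synthetic_families_no_loss_full_recovery(self, species_tree, node_ages):
        for origin in ("Filozoa", "Holozoa", "Opisthokonta", "Unikonta", "Paneukaryotic"):
            presence, _ = generate_family_history(species_tree, origin, 0.0, seed=1)
            node = dollo_origin(presence, species_tree)
            assert SpeciesTree.node_label(node) == origin


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration with
    exact rational arithmetic."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    def pmf(x):
        return (Fraction(math.comb(col1, x) * math.comb(n - col1, row1 - x),
                         math.comb(n, row1)))
    p_obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = pmf(x)
        if px <= p_obs * (1 + Fraction(1, 10**12)):
            total += px
    return float(min(total, 1))


class TestFisher:
    @pytest.mark.parametrize("table", [
        (8, 2, 20, 70), (0, 10, 5, 5), (3, 3, 3, 3), (1, 0, 0, 1), (5, 15, 10, 10),
    ])
    def test_matches_enumeration_oracle(self, table):
        _, p = fisher_two_sided(*table)
        assert abs(p - fisher_oracle(*table)) < 1e-10

    def test_identical_distribution_p_one(self, species_tree, node_ages):
        universe = OrthogroupUniverse({
            "OG1": {"Cowc": ["c1", "c2"], "Atha": ["a1"]},
            "OG2": {"Cowc": ["c3", "c4"], "Mvib": ["m1"]},
        })
        ages = assign_ages(universe, species_tree, node_ages)
        cluster = {"c1", "c3"}          # one gene of each age
        background = {"c1", "c2", "c3", "c4"}
        out = age_enrichment(cluster, background, ages, age_classes=[1, 5])
        assert (out["p"] == 1.0).all()
        assert np.allclose(out["enrichment_ratio"], 1.0)

    def test_bonferroni_arithmetic(self):
        ages = DolloAgeMap(gene_age={"a": 0, "b": 1, "c": 0, "d": 1})
        out = age_enrichment({"a", "b"}, {"a", "b", "c", "d"}, ages,
                             n_tests=30, age_classes=[0])
        assert out.loc[0, "p_bonferroni"] == pytest.approx(min(1.0, out.loc[0, "p"] * 30))

    def test_table_counts_consistent(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(60)]
        ages = DolloAgeMap(gene_age={g: int(rng.integers(0, 6)) for g in genes})
        clusters = {"c1": set(genes[:20]), "c2": set(genes[20:35])}
        out = age_enrichment_table(clusters, set(genes), ages)
        for name, genes_c in clusters.items():
            sub = out[out.cluster == name]
            assert sub["cluster_count"].sum() == len(genes_c)

    def test_empty_cluster_rejected(self):
        ages = DolloAgeMap(gene_age={"a": 0})
        with pytest.raises(ValueError):
            age_enrichment(set(), {"a"}, ages)
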