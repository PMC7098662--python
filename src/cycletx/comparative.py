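"""Cross-species overlap of periodic orthogroups.

For a pair of species the test takes the orthogroups common to both (C),
counts each species' periodic orthogroups within them (p1, p2), and compares
the observed number periodic in both against the chance expectation
A_exp = p1*p2/C.  The null model is X ~ Binomial(C, (p1/C)(p2/C)) — the
unique binomial over the common universe with mean A_exp — with a one-sided
(enrichment) p-value; a Fisher/hypergeometric variant on the same 2x2 is
available for sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import binom, fisher_exact

logger = logging.getLogger("cycletx.comparative")

__all__ = [
    "OrthogroupUniverse",
    "OverlapTestResult",
    "SpeciesPeriodicList",
    "periodic_orthogroups",
    "overlap_pvalue",
    "pairwise_overlap_test",
    "one_to_one_overlap_test",
    "core_conserved_set",
    "apply_species_threshold",
]


@dataclass
class OrthogroupUniverse:
    """Orthogroup membership: orthogroup id -> species -> gene list.

    All tables compared against each other must come from one joint
    orthology inference so that ids share a single space.
    """

    members: dict[str, dict[str, list[str]]]

    def __post_init__(self) -> None:
        self._gene_to_og: dict[str, dict[str, str]] = {}
        for og, per_species in self.members.items():
            for sp, genes in per_species.items():
                bucket = self._gene_to_og.setdefault(sp, {})
                for g in genes:
                    if g in bucket:
                        raise ValueError(
                            f"gene {g!r} of species {sp!r} occurs in orthogroups "
                            f"{bucket[g]!r} and {og!r}"
                        )
                    bucket[g] = og

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.members)

    @property
    def species(self) -> list[str]:
        out = set()
        for per_species in self.members.values():
            out.update(per_species)
        return sorted(out)

    def present_in(self, species: str) -> set[str]:
        return {og for og, m in self.members.items() if m.get(species)}

    def orthogroup_of(self, species: str, gene: str) -> str | None:
        return self._gene_to_og.get(species, {}).get(gene)

    def genes_of(self, species: str) -> set[str]:
        return set(self._gene_to_og.get(species, {}))


@dataclass
class SpeciesPeriodicList:
    """Periodic gene ids of one dataset (species or cell type), after the
    per-species fraction threshold."""

    species: str
    dataset: str
    periodic_genes: list[str]
    total_genes: int
    threshold: float

    def __post_init__(self) -> None:
        if self.total_genes > 0 and len(self.periodic_genes) / self.total_genes > self.threshold:
            raise ValueError("periodic list exceeds the species threshold")


@dataclass
class OverlapTestResult:
    species_pair: tuple[str, str]
    C: int
    p1: int
    p2: int
    shared: int
    A_exp: float
    binom_p: float
    method: str = "binomial"

    def to_dict(self) -> dict:
        return {
            "species_a": self.species_pair[0], "species_b": self.species_pair[1],
            "C": self.C, "p1": self.p1, "p2": self.p2, "shared": self.shared,
            "A_exp": self.A_exp, "binom_p": self.binom_p, "method": self.method,
        }


def apply_species_threshold(ranked_genes: list[str], total: int, threshold: float) -> list[str]:
    """Keep at most floor(threshold * total) best-ranked genes."""
    if not ranked_genes:
        raise ValueError("empty gene list")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    cap = math.floor(threshold * total)
    return list(ranked_genes[:cap])


def periodic_orthogroups(plist: SpeciesPeriodicList, universe: OrthogroupUniverse) -> set[str]:
    """Orthogroups with at least one periodic member gene of the species."""
    if plist.species not in universe.species:
        raise ValueError(f"species {plist.species!r} not in the orthogroup table")
    out = set()
    unmapped = 0
    for g in plist.periodic_genes:
        og = universe.orthogroup_of(plist.species, g)
        if og is None:
            unmapped += 1
        else:
            out.add(og)
    if unmapped:
        logger.info("periodic_orthogroups: %d periodic genes of %s map to no orthogroup",
                    unmapped, plist.species)
    return out


def overlap_pvalue(C: int, p1: int, p2: int, shared: int, method: str = "binomial") -> float:
    """One-sided (enrichment) p-value for ``shared`` periodic orthogroups out
    of ``C`` in common, given each species' periodic counts p1 and p2.

    binomial: P(X >= shared) for X ~ Binomial(C, (p1/C)(p2/C)), the unique
    binomial over the common universe with mean p1*p2/C.  fisher: one-sided
    hypergeometric on the 2x2 of periodic-in-A x periodic-in-B within C.
    """
    if p1 == 0 or p2 == 0:
        return 1.0
    if method == "binomial":
        q = (p1 / C) * (p2 / C)
        return float(binom.sf(shared - 1, C, q))
    if method == "fisher":
        table = [[shared, p1 - shared], [p2 - shared, C - p1 - p2 + shared]]
        return float(fisher_exact(table, alternative="greater")[1])
    raise ValueError(f"unknown method {method!r}")


def pairwise_overlap_test(
    periodic_a: set[str], periodic_b: set[str],
    universe_a: set[str], universe_b: set[str],
    labels: tuple[str, str] = ("A", "B"),
    method: str = "binomial",
) -> OverlapTestResult:
    """One-sided enrichment test of shared periodic orthogroups for a species
    pair; all four sets are orthogroup ids from one shared id space."""
    common = universe_a & universe_b
    C = len(common)
    if C == 0:
        raise ValueError("no orthogroups in common")
    p1 = len(periodic_a & common)
    p2 = len(periodic_b & common)
    shared = len(periodic_a & periodic_b & common)
    a_exp = p1 * p2 / C
    p = overlap_pvalue(C, p1, p2, shared, method)
    return OverlapTestResult(labels, C, p1, p2, shared, a_exp, p, method)


def one_to_one_overlap_test(
    pairs: list[tuple[str, str]],
    periodic_a: set[str], periodic_b: set[str],
    labels: tuple[str, str] = ("A", "B"),
    method: str = "binomial",
) -> OverlapTestResult:
    """Same statistic on a one-to-one ortholog pair list (gene level);
    C is the number of pairs."""
    left = [a for a, _ in pairs]
    right = [b for _, b in pairs]
    if len(set(left)) != len(left) or len(set(right)) != len(right):
        dup = sorted({g for g in left if left.count(g) > 1}
                     | {g for g in right if right.count(g) > 1})
        raise ValueError(f"duplicated genes in one-to-one pair list: {dup[:5]}")
    C = len(pairs)
    if C == 0:
        raise ValueError("empty pair list")
    p1 = sum(1 for a, _ in pairs if a in periodic_a)
    p2 = sum(1 for _, b in pairs if b in periodic_b)
    shared = sum(1 for a, b in pairs if a in periodic_a and b in periodic_b)
    a_exp = p1 * p2 / C
    p = overlap_pvalue(C, p1, p2, shared, method)
    return OverlapTestResult(labels, C, p1, p2, shared, a_exp, p, method)


def core_conserved_set(
    universe: OrthogroupUniverse,
    periodic_by_species: dict[str, list[set[str]]],
) -> set[str]:
    """Orthogroups present in every species and periodic in at least one
    dataset of every species.

    ``periodic_by_species`` maps species -> list of per-dataset periodic
    orthogroup-id sets.
    """
    if len(periodic_by_species) < 2:
        raise ValueError("need at least 2 species")
    for sp, datasets in periodic_by_species.items():
        if not datasets:
            raise ValueError(f"species {sp!r} has no datasets")
    core: set[str] | None = None
    for sp, datasets in periodic_by_species.items():
        ok = universe.present_in(sp) & set().union(*datasets)
        core = ok if core is None else core & ok
    return core if core is not None else set()


def overlap_table(results: list[OverlapTestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])
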