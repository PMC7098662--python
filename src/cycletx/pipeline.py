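"""End-to-end pipeline: detection -> clustering -> ages -> enrichment -> overlap.

``run_pipeline`` wires the stage functions together from a
``PipelineConfig``, writes every stage's tables plus a JSON manifest to the
output directory, and halts with a ``PipelineStageError`` naming the stage
on failure.  Downstream stages (ages, enrichment, comparison) run only when
their inputs are configured.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .clustering import (assign_phase_labels, cluster_agreement, cluster_mean_profiles,
                         hierarchical_clusters, kmeans_clusters, DEFAULT_PHASE_WINDOWS)
from .gene_age import age_enrichment_table, assign_ages
from .enrichment import parent_child_union, term_for_term
from .comparative import (SpeciesPeriodicList, pairwise_overlap_test,
                          periodic_orthogroups, overlap_table)
from .periodicity import (PeriodicityParams, SelectionRule, average_replicates,
                          filter_expressed, periodicity_pvalues, rank_and_combine,
                          select_periodic, zscore_normalize, ExpressionTimeCourse)
from . import io as cio

logger = logging.getLogger("cycletx.pipeline")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "detect_periodic_genes"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    rep1_path: str = ""
    rep2_path: str = ""
    out_dir: str = "cycletx_out"
    expression_threshold_tpm: float = 1.0
    params: PeriodicityParams = field(default_factory=PeriodicityParams)
    rule: SelectionRule = field(default_factory=SelectionRule)
    k: int = 5
    linkage: str = "complete"
    phase_windows: list = field(default_factory=lambda: list(DEFAULT_PHASE_WINDOWS))
    # optional stage inputs
    tree_path: str = ""
    focal_species: str = ""
    orthogroups_path: str = ""
    node_age_path: str = ""
    gene2term_path: str = ""
    obo_path: str = ""
    periodic_lists: dict = field(default_factory=dict)  # species -> gene-list path
    species_thresholds: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class PipelineResult:
    tables: dict = field(default_factory=dict)
    selected: list = field(default_factory=list)
    hierarchical: object = None
    kmeans: object = None
    agreement: object = None
    ages: object = None
    age_enrichment: object = None
    term_enrichment: object = None
    overlaps: object = None


def detect_periodic_genes(
    replicates: list[ExpressionTimeCourse],
    params: PeriodicityParams,
    rule: SelectionRule,
    threshold_tpm: float = 1.0,
):
    """Filter, test both replicates and their average, rank, and select.

    The average dataset is the mean of tpm values, filtered and tested
    independently; the common gene universe for ranking is the intersection
    of the three filtered sets.  Returns (selected genes, tables dict,
    average time course restricted to the universe).
    """
    if len(replicates) != 2:
        raise ValueError("expected exactly two replicates")
    avg = average_replicates(replicates)
    datasets = {"rep1": replicates[0], "rep2": replicates[1], "average": avg}
    filtered = {name: filter_expressed(tc, threshold_tpm) for name, tc in datasets.items()}
    universe = set.intersection(*(set(tc.gene_ids) for tc in filtered.values()))
    tables = {}
    for name, tc in filtered.items():
        keep = [g in universe for g in tc.gene_ids]
        sub = ExpressionTimeCourse(
            gene_ids=[g for g in tc.gene_ids if g in universe],
            times=tc.times, values=tc.values[keep],
            replicate_label=tc.replicate_label)
        pv = periodicity_pvalues(sub, params)
        pv = pv.set_index("gene_id")
        tables[name] = rank_and_combine(pv["p_jtk"], pv["p_rain"])
    selected = select_periodic(tables["rep1"], tables["rep2"], tables["average"], rule)
    for name in tables:
        tables[name]["selected"] = tables[name]["gene_id"].isin(set(selected))
    avg_universe = filtered["average"]
    keep = [g in universe for g in avg_universe.gene_ids]
    avg_sub = ExpressionTimeCourse(
        gene_ids=[g for g in avg_universe.gene_ids if g in universe],
        times=avg_universe.times, values=avg_universe.values[keep],
        replicate_label="average")
    return selected, tables, avg_sub


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    params_meta = {
        "threshold_tpm": config.expression_threshold_tpm,
        "periods": ",".join(map(str, config.params.period_grid_samples)),
        "rain_period": config.params.rain_period_samples,
        "interval_h": config.params.sample_interval_hours,
        "loose": config.rule.loose_cutoff, "strict": config.rule.strict_cutoff,
        "k": config.k, "linkage": config.linkage, "seed": config.seed,
        "combine": config.params.combine, "n_permutations": config.params.n_permutations,
    }

    stage = "detect"
    try:
        reps = [cio.read_expression_tsv(config.rep1_path, "rep1"),
                cio.read_expression_tsv(config.rep2_path, "rep2")]
        selected, tables, avg = detect_periodic_genes(
            reps, config.params, config.rule, config.expression_threshold_tpm)
        result.tables = tables
        result.selected = selected
        for name, table in tables.items():
            cio.write_table_tsv(table, out_dir / f"periodicity_{name}.tsv", params_meta)
        cio.write_gene_list(selected, out_dir / "selected_genes.txt")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineStageError(stage, str(exc)) from exc

    stage = "cluster"
    try:
        keep = [g in set(selected) for g in avg.gene_ids]
        profiles = ExpressionTimeCourse(
            gene_ids=[g for g, k in zip(avg.gene_ids, keep) if k],
            times=avg.times, values=avg.values[keep], replicate_label="average")
        profiles = zscore_normalize(profiles)
        result.hierarchical = assign_phase_labels(
            hierarchical_clusters(profiles, config.k, config.linkage), config.phase_windows)
        result.kmeans = assign_phase_labels(
            kmeans_clusters(profiles, config.k, seed=config.seed), config.phase_windows)
        result.agreement = cluster_agreement(result.hierarchical, result.kmeans)
        cio.write_table_tsv(result.hierarchical.to_frame(),
                            out_dir / "clusters_hierarchical.tsv", params_meta)
        cio.write_table_tsv(result.kmeans.to_frame(), out_dir / "clusters_kmeans.tsv", params_meta)
        cio.write_table_tsv(cluster_mean_profiles(profiles, result.hierarchical).reset_index(names="cluster"),
                            out_dir / "cluster_mean_profiles.tsv", params_meta)
        cio.write_table_tsv(result.agreement.reset_index(names="hier_cluster"),
                            out_dir / "cluster_agreement.tsv", params_meta)
    except Exception as exc:
        raise PipelineStageError(stage, str(exc)) from exc

    universe = None
    if config.orthogroups_path:
        stage = "orthogroups"
        try:
            universe = cio.read_orthogroups_tsv(config.orthogroups_path)
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

    if config.tree_path:
        stage = "gene_age"
        try:
            if universe is None:
                raise ValueError("gene-age stage needs an orthogroup table")
            if not config.focal_species:
                raise ValueError("gene-age stage needs a focal species")
            tree = cio.read_species_tree(config.tree_path, config.focal_species)
            node_ages = cio.read_node_age_map(config.node_age_path)
            result.ages = assign_ages(universe, tree, node_ages)
            background = set(universe.genes_of(config.focal_species)) | set(selected)
            clusters = {f"cluster_{c}": result.hierarchical.members(c)
                        for c in range(1, config.k + 1)}
            clusters["non_periodic"] = background - set(selected)
            result.age_enrichment = age_enrichment_table(clusters, background, result.ages)
            cio.write_table_tsv(result.age_enrichment, out_dir / "age_enrichment.tsv", params_meta)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

    if config.gene2term_path:
        stage = "enrich"
        try:
            ann = cio.read_annotation_map(config.gene2term_path, config.obo_path or None)
            population = set(selected)
            parts = []
            for c in range(1, config.k + 1):
                study = result.hierarchical.members(c)
                tab = (parent_child_union(study, population, ann)
                       if config.obo_path else term_for_term(study, population, ann))
                tab.insert(0, "cluster", c)
                parts.append(tab)
            import pandas as pd
            result.term_enrichment = pd.concat(parts, ignore_index=True)
            cio.write_table_tsv(result.term_enrichment, out_dir / "term_enrichment.tsv", params_meta)
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

    if config.periodic_lists:
        stage = "compare"
        try:
            if universe is None:
                raise ValueError("comparison stage needs an orthogroup table")
            per_species = {}
            for sp, path in config.periodic_lists.items():
                genes = cio.read_gene_list(path)
                thr = config.species_thresholds.get(sp, 0.10)
                total = len(universe.genes_of(sp)) or len(genes)
                genes = genes[: int(thr * total)] if len(genes) > thr * total else genes
                plist = SpeciesPeriodicList(sp, "default", genes, total, thr)
                per_species[sp] = periodic_orthogroups(plist, universe)
            results = []
            species = sorted(per_species)
            for i, a in enumerate(species):
                for b in species[i + 1:]:
                    results.append(pairwise_overlap_test(
                        per_species[a], per_species[b],
                        universe.present_in(a), universe.present_in(b), labels=(a, b)))
            result.overlaps = overlap_table(results)
            cio.write_table_tsv(result.overlaps, out_dir / "overlap_tests.tsv", params_meta)
        except Exception as exc:
            raise PipelineStageError(stage, str(exc)) from exc

    cio.write_manifest(
        out_dir / "manifest.json",
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        config={k: v for k, v in dataclasses.asdict(config).items()},
        n_selected=len(result.selected),
    )
    return result
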