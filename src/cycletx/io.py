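"""Readers and writers for the pipeline's plain-text formats.

Expression matrices, result tables and gene lists are TSV; species trees are
newick; ontologies are OBO (parsed with obonet); orthogroup tables follow
the OrthoFinder layout (first column the orthogroup id, one column per
species, comma-separated gene ids, empty cell = absent).  Output tables
carry ``#``-prefixed header comments recording the parameters that produced
them; readers skip such lines.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .comparative import OrthogroupUniverse
from .enrichment import AnnotationMap
from .gene_age import SpeciesTree
from .periodicity import ExpressionTimeCourse

logger = logging.getLogger("cycletx.io")

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_table_tsv", "write_table_tsv",
    "read_gene_list", "write_gene_list",
    "read_orthogroups_tsv", "read_species_tree",
    "read_node_age_map", "read_annotation_map",
    "read_config", "write_config", "write_manifest",
]


class ParseError(ValueError):
    """Malformed input file."""


def _comment_params(params: dict | None) -> str:
    if not params:
        return ""
    items = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    return f"# {items}\n"


# -- expression matrices ----------------------------------------------------

_TIME_RE = re.compile(r"^[A-Za-z_]*([0-9]+(?:\.[0-9]+)?)$")


def read_expression_tsv(path: str | Path, replicate_label: str = "") -> ExpressionTimeCourse:
    """Read a genes x time-points tpm matrix.

    The header row holds time labels like ``t2.00`` (any non-numeric prefix
    is stripped); the first column holds unique gene ids.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a gene-id column plus time columns")
    gene_col = df.columns[0]
    times = []
    for col in df.columns[1:]:
        m = _TIME_RE.match(col.strip())
        if not m:
            raise ParseError(f"{path}: cannot parse time from column label {col!r}")
        times.append(float(m.group(1)))
    gene_ids = df[gene_col].tolist()
    dup = df[gene_col][df[gene_col].duplicated()].tolist()
    if dup:
        raise ParseError(f"{path}: duplicate gene id(s) {sorted(set(dup))[:5]}")
    values = np.empty((len(gene_ids), len(times)))
    for ci, col in enumerate(df.columns[1:]):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(parsed.isna().to_numpy())
        if bad.size:
            r = int(bad[0])
            raise ParseError(f"{path}: non-numeric value {df[col].iloc[r]!r} at "
                             f"row {r + 2} (gene {gene_ids[r]}), column {col!r}")
        neg = np.flatnonzero((parsed < 0).to_numpy())
        if neg.size:
            r = int(neg[0])
            raise ParseError(f"{path}: negative value {parsed.iloc[r]} at "
                             f"row {r + 2} (gene {gene_ids[r]}), column {col!r}")
        values[:, ci] = parsed.to_numpy()
    label = replicate_label or path.stem
    return ExpressionTimeCourse(gene_ids=gene_ids, times=np.array(times),
                                values=values, replicate_label=label)


def write_expression_tsv(tc: ExpressionTimeCourse, path: str | Path,
                         params: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_params(params))
        cols = "\t".join(f"t{t:.2f}" for t in tc.times)
        fh.write(f"gene_id\t{cols}\n")
        for g, row in zip(tc.gene_ids, tc.values):
            vals = "\t".join(format(v, ".6g") for v in row)
            fh.write(f"{g}\t{vals}\n")


# -- generic result tables and gene lists -----------------------------------

def write_table_tsv(df: pd.DataFrame, path: str | Path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_comment_params(params))
        df.to_csv(fh, sep="\t", index=False)


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_gene_list(path: str | Path) -> list[str]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


# -- orthogroups, trees, ontologies -----------------------------------------

def read_orthogroups_tsv(path: str | Path) -> OrthogroupUniverse:
    """OrthoFinder-style table: Orthogroup<TAB>species1<TAB>species2..."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    og_col = df.columns[0]
    species = list(df.columns[1:])
    members: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        per_species = {}
        for sp in species:
            cell = row[sp].strip()
            if cell:
                per_species[sp] = [g.strip() for g in cell.split(",") if g.strip()]
        members[row[og_col]] = per_species
    return OrthogroupUniverse(members)


def write_orthogroups_tsv(universe: OrthogroupUniverse, path: str | Path) -> None:
    species = universe.species
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(species) + "\n")
        for og in universe.orthogroup_ids:
            cells = [", ".join(universe.members[og].get(sp, [])) for sp in species]
            fh.write(og + "\t" + "\t".join(cells) + "\n")


def read_species_tree(path: str | Path, focal_species: str) -> SpeciesTree:
    return SpeciesTree.from_newick(Path(path).read_text(), focal_species)


def read_node_age_map(path: str | Path) -> dict[str, int]:
    """Two-column TSV: node label -> integer age class."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}: expected two tab-separated columns, got {line!r}")
        out[parts[0]] = int(parts[1])
    return out


def read_annotation_map(gene2term_path: str | Path, obo_path: str | Path | None = None,
                        relations: tuple[str, ...] = ("is_a", "part_of")) -> AnnotationMap:
    """Gene->term two-column TSV plus an optional OBO ontology; only the
    requested edge types are kept in the DAG."""
    gene_to_terms: dict[str, set[str]] = {}
    for line in Path(gene2term_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{gene2term_path}: expected gene<TAB>term, got {line!r}")
        gene_to_terms.setdefault(parts[0], set()).add(parts[1])
    graph = nx.DiGraph()
    if obo_path is not None:
        raw = obonet.read_obo(str(obo_path))
        for child, parent, key in raw.edges(keys=True):
            if key in relations:
                graph.add_edge(child, parent)
    return AnnotationMap(gene_to_terms=gene_to_terms, ontology=graph)


# -- flat config and manifests ----------------------------------------------

def write_config(obj, path: str | Path) -> None:
    """Flat key=value serialization of a (dataclass) configuration."""
    d = dataclasses.asdict(obj) if dataclasses.is_dataclass(obj) else dict(obj)
    with open(path, "w") as fh:
        for k, v in d.items():
            if isinstance(v, (tuple, list)):
                v = ",".join(str(x) for x in v)
            fh.write(f"{k}={v}\n")


def read_config(path: str | Path) -> dict[str, str]:
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"{path}: expected key=value, got {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def write_manifest(path: str | Path, **entries) -> None:
    Path(path).write_text(json.dumps(entries, indent=2, default=str) + "\n")
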