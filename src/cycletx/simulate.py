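"""Synthetic data with known ground truth for the whole pipeline.

Three generators are provided:

* ``generate_timecourse`` — replicate expression matrices from a synchronized
  culture released into the cycle: a damped cosine on a positive baseline
  with i.i.d. Gaussian noise, clipped at zero.  Damping emulates the
  progressive loss of synchrony of the culture.
* ``generate_orthogroup_universe`` — toy cross-species orthogroup tables with
  independent (null) or planted-shared periodic labels.
* ``generate_family_history`` — presence/absence of a gene family over the
  leaves of a species tree under a single gain and random clade losses,
  with the true origin recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .periodicity import ExpressionTimeCourse
from .comparative import OrthogroupUniverse
from .gene_age import SpeciesTree

logger = logging.getLogger("cycletx.simulate")

__all__ = [
    "SimulationConfig",
    "generate_timecourse",
    "generate_orthogroup_universe",
    "generate_family_history",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of the simulated time course.

    Defaults mirror a synchronized-culture design: 16 samples every 0.75 h
    from 2 h after release, two replicates, ~10% of genes periodic with one
    ~11 h oscillation over the series, amplitudes damped at ``damping_rate``
    per hour as synchrony decays.  Periodic amplitudes are drawn uniformly
    from ``amplitude_range`` (tpm) against ``noise_sd`` tpm of additive
    noise; baselines are log-uniform over ``baseline_range``.  A fraction
    ``drift_fraction`` of the non-periodic genes carries a linear trend, to
    exercise specificity against monotone drift.
    """

    n_genes: int = 2000
    periodic_fraction: float = 0.1
    n_timepoints: int = 16
    t_start_hours: float = 2.0
    interval_hours: float = 0.75
    period_hours: float = 11.0
    damping_rate: float = 0.05
    noise_sd: float = 1.0
    amplitude_range: tuple[float, float] = (2.0, 4.0)
    baseline_range: tuple[float, float] = (5.0, 50.0)
    drift_fraction: float = 0.05
    drift_slope_sd: float = 0.15
    replicate_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.periodic_fraction <= 1:
            raise ValueError("periodic_fraction must be in [0, 1]")
        if self.n_timepoints < 4:
            raise ValueError("n_timepoints must be >= 4")
        if self.interval_hours <= 0:
            raise ValueError("interval_hours must be > 0")
        if self.damping_rate < 0:
            raise ValueError("damping_rate must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return self.t_start_hours + self.interval_hours * np.arange(self.n_timepoints)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        """Rebuild a config from flat string key=value pairs (file round-trip)."""
        import dataclasses

        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in mapping:
                continue
            v = mapping[f.name]
            if isinstance(v, str):
                if f.name in ("amplitude_range", "baseline_range"):
                    v = tuple(float(x) for x in v.split(","))
                elif f.name in ("n_genes", "n_timepoints", "replicate_count", "seed"):
                    v = int(v)
                else:
                    v = float(v)
            kwargs[f.name] = v
        return cls(**kwargs)


def generate_timecourse(config: SimulationConfig) -> tuple[list[ExpressionTimeCourse], pd.DataFrame]:
    """Simulate replicate tpm matrices plus the per-gene truth table.

    Each gene g follows  x_g(t) = b_g + A_g cos(2pi (t - phi_g)/P) e^{-lam (t - t0)} + eps,
    clipped at zero; the deterministic part (baseline, amplitude, phase) is
    shared between replicates, the noise is drawn independently per
    replicate.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    t = config.times

    n_periodic = int(round(config.periodic_fraction * n))
    is_periodic = np.zeros(n, dtype=bool)
    is_periodic[:n_periodic] = True

    gene_ids = [f"g{i:05d}" for i in range(n)]
    baseline = np.exp(rng.uniform(np.log(config.baseline_range[0]),
                                  np.log(config.baseline_range[1]), size=n))
    amplitude = np.where(
        is_periodic,
        rng.uniform(config.amplitude_range[0], config.amplitude_range[1], size=n),
        0.0,
    )
    phase = np.where(is_periodic, rng.uniform(0.0, config.period_hours, size=n), 0.0)

    # monotone drift on a fraction of the non-periodic genes
    drifting = np.zeros(n, dtype=bool)
    nonper = np.flatnonzero(~is_periodic)
    n_drift = int(round(config.drift_fraction * nonper.size))
    drifting[nonper[:n_drift]] = True
    slope = np.where(drifting, rng.normal(0.0, config.drift_slope_sd, size=n), 0.0)

    damp = np.exp(-config.damping_rate * (t - config.t_start_hours))
    signal = (
        baseline[:, None]
        + amplitude[:, None] * np.cos(2 * np.pi * (t[None, :] - phase[:, None]) / config.period_hours) * damp[None, :]
        + slope[:, None] * (t[None, :] - config.t_start_hours)
    )

    replicates = []
    for r in range(config.replicate_count):
        noise = rng.normal(0.0, config.noise_sd, size=(n, len(t))) if config.noise_sd > 0 else 0.0
        values = np.clip(signal + noise, 0.0, None)
        replicates.append(ExpressionTimeCourse(
            gene_ids=gene_ids, times=t, values=values,
            replicate_label=f"rep{r + 1}",
        ))

    constant = np.array([
        all(np.all(rep.values[i] == rep.values[i, 0]) for rep in replicates)
        for i in range(n)
    ])
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "is_periodic": is_periodic,
        "amplitude": amplitude,
        "phase_hours": phase,
        "baseline": baseline,
        "period_hours": config.period_hours,
        "drifting": drifting,
        "constant": constant,
    })
    return replicates, truth


def generate_orthogroup_universe(
    n_species: int,
    n_orthogroups: int,
    presence_prob: float,
    periodic_prob_per_species: list[float],
    shared_periodic_excess: float = 0.0,
    seed: int = 0,
) -> tuple[OrthogroupUniverse, dict[str, set[str]], set[str]]:
    """Toy orthogroup universe with per-species periodic gene labels.

    With ``shared_periodic_excess`` = 0 the periodic labels are independent
    Bernoulli draws per species (the null of the overlap test); otherwise
    that fraction of orthogroups is forced present and periodic in every
    species.  Returns the universe, per-species periodic gene sets, and the
    ids of the planted shared-periodic orthogroups.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    probs = list(periodic_prob_per_species)
    if len(probs) != n_species:
        raise ValueError("periodic_prob_per_species must have one entry per species")
    for p in [presence_prob, shared_periodic_excess, *probs]:
        if not 0 <= p <= 1:
            raise ValueError("probabilities must be in [0, 1]")

    rng = np.random.default_rng(seed)
    species = [f"sp{s + 1}" for s in range(n_species)]
    og_ids = [f"OG{i:06d}" for i in range(n_orthogroups)]
    n_planted = int(round(shared_periodic_excess * n_orthogroups))
    planted = set(og_ids[:n_planted])

    present = rng.random((n_orthogroups, n_species)) < presence_prob
    periodic = np.zeros((n_orthogroups, n_species), dtype=bool)
    for s, p in enumerate(probs):
        periodic[:, s] = present[:, s] & (rng.random(n_orthogroups) < p)
    present[:n_planted, :] = True
    periodic[:n_planted, :] = True

    members: dict[str, dict[str, list[str]]] = {}
    periodic_genes: dict[str, set[str]] = {sp: set() for sp in species}
    for i, og in enumerate(og_ids):
        row = {}
        for s, sp in enumerate(species):
            if present[i, s]:
                gene = f"{sp}_{og}"
                row[sp] = [gene]
                if periodic[i, s]:
                    periodic_genes[sp].add(gene)
        if row:
            members[og] = row
    universe = OrthogroupUniverse(members)
    return universe, periodic_genes, planted


def generate_family_history(
    tree: SpeciesTree,
    origin_node: str,
    loss_prob: float,
    seed: int = 0,
) -> tuple[set[str], str]:
    """Presence/absence of a gene family under single gain + random losses.

    The family is gained on ``origin_node`` (an internal node label or leaf
    taxon) and then lost independently with probability ``loss_prob`` on
    every branch below the origin, except along the path to the focal
    species, which always retains it.  Returns (present leaf labels, origin).
    """
    if not 0 <= loss_prob <= 1:
        raise ValueError("loss_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    origin = tree.find_node(origin_node)
    focal_leaf = tree.find_node(tree.focal_species)
    protected = set()
    node = focal_leaf
    while node is not None:
        protected.add(id(node))
        node = node.parent_node
    if id(origin) not in protected and origin is not focal_leaf:
        raise ValueError(f"origin {origin_node!r} is not an ancestor of the focal species")

    present: set[str] = set()

    def descend(node) -> None:
        if node.is_leaf():
            present.add(node.taxon.label)
            return
        for child in node.child_nodes():
            if id(child) in protected:
                descend(child)
            elif rng.random() >= loss_prob:
                descend(child)

    descend(origin)
    return present, origin_node
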