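"""Synthetic studies with planted differential edges and a predictive pair.

The generator emulates the statistical structure the pipeline assumes in a
bulk RNA-Seq cohort stratified into three unequal histological subgroups
(default sizes 49/18/16): log-scale expression with gene-specific
baselines, subgroup-specific linear relations on planted network edges, a
binary treatment response driven by a planted two-gene interaction term,
and an age-like numeric covariate.  A scaffold curated network (planted
edges plus an Erdos-Renyi background over independent genes) and toy gene
sets are emitted alongside, so every pipeline stage is testable without
external data.

It does not emulate count-level RNA-Seq noise (negative binomial counts,
library-size effects) or batch structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io_formats import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotation,
    write_expression,
    write_gmt,
    write_interactions,
)
from .network_core import Edge, InteractionNetwork, canonical_edge

DEFAULT_GROUP_SIZES = {
    "lympho_myeloid": 49,
    "diffuse_myeloid": 18,
    "pauci_immune_fibroid": 16,
}
DEFAULT_SLOPES = {
    "lympho_myeloid": 1.0,
    "diffuse_myeloid": 0.0,
    "pauci_immune_fibroid": 0.0,
}


@dataclass
class SimulationConfig:
    """Study-generating parameters.

    Defaults mirror a three-subgroup early-arthritis cohort: unequal
    subgroup sizes 49/18/16, an age covariate of mean 52.1 / sd 15.9 years,
    unit residual noise on log-scale expression, and a planted response
    pair with a log-odds coefficient of 2 on its standardized interaction
    term.
    """

    n_genes: int = 200
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_planted_edges: int = 5
    slope_per_group: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    noise_sd: float = 1.0
    response_effect: float = 2.0
    age_effect: float = 0.5
    age_mean: float = 52.1
    age_sd: float = 15.9
    moderate_fraction: float = 0.0
    n_background_edges: int = 150
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2 * self.n_planted_edges + 2:
            raise ConfigError("n_genes too small for the requested planted structure")
        if any(n < 3 for n in self.group_sizes.values()):
            raise ConfigError("every subgroup needs >= 3 samples")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if set(self.slope_per_group) != set(self.group_sizes):
            raise ConfigError("slope_per_group must cover exactly the subgroups")
        if not 0 <= self.moderate_fraction < 1:
            raise ConfigError("moderate_fraction must lie in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated study."""

    planted_edges: list[tuple[Edge, dict[str, float]]]
    planted_response_pair: Edge
    response_effect: float
    seed: int


def simulate_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, InteractionNetwork, GeneSetCollection, SimulationTruth]:
    """Generate one study; bitwise reproducible for a given seed.

    Baseline log-expression of gene g in every sample is Normal(mu_g, 1)
    with mu_g ~ Uniform(2, 10).  For each planted edge (x, y) the second
    gene is overwritten within subgroup k as y = mu_y + b_k * (x - mu_x) +
    Normal(0, noise_sd).  The response pair (z1, z2) consists of two
    independent genes; response is Bernoulli(logistic(beta * t + gamma *
    age_std)) with t the standardized centered product of z1 and z2.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = [f"G{i:04d}" for i in range(1, config.n_genes + 1)]
    sample_ids, groups = [], []
    for label, n in config.group_sizes.items():
        for _ in range(n):
            sample_ids.append(f"S{len(sample_ids) + 1:03d}")
            groups.append(label)
    n_samples = len(sample_ids)
    groups = pd.Series(groups, index=sample_ids, name="subgroup")

    mu = rng.uniform(2.0, 10.0, size=config.n_genes)
    values = mu[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, n_samples))

    # planted differential edges, then a dedicated response pair
    picked = rng.choice(config.n_genes, size=2 * config.n_planted_edges + 2, replace=False)
    planted_edges: list[tuple[Edge, dict[str, float]]] = []
    gene_index = {g: i for i, g in enumerate(genes)}
    for e in range(config.n_planted_edges):
        xi, yi = int(picked[2 * e]), int(picked[2 * e + 1])
        if genes[xi] > genes[yi]:
            # orient the planted relation from the lexicographically earlier
            # gene to the later one, matching the edge scan's orientation
            xi, yi = yi, xi
        x = values[xi]
        y = np.empty(n_samples)
        for label in config.group_sizes:
            mask = (groups == label).to_numpy()
            b = config.slope_per_group[label]
            y[mask] = mu[yi] + b * (x[mask] - mu[xi]) + rng.normal(
                0.0, config.noise_sd, size=int(mask.sum())
            )
        values[yi] = y
        # stored in planted (predictor, response) order, not canonical order
        planted_edges.append(((genes[xi], genes[yi]), dict(config.slope_per_group)))

    z1i, z2i = int(picked[-2]), int(picked[-1])
    response_pair = canonical_edge(genes[z1i], genes[z2i])

    age = rng.normal(config.age_mean, config.age_sd, size=n_samples)
    age_std = (age - age.mean()) / age.std(ddof=0)
    t = (values[z1i] - values[z1i].mean()) * (values[z2i] - values[z2i].mean())
    t_sd = t.std(ddof=0)
    t_std = t / t_sd if t_sd > 0 else t
    eta = config.response_effect * t_std + config.age_effect * age_std
    prob = 1.0 / (1.0 + np.exp(-eta))
    response = np.where(rng.random(n_samples) < prob, "Good", "None").astype(object)
    if config.moderate_fraction > 0:
        n_mod = int(round(config.moderate_fraction * n_samples))
        mod_idx = rng.choice(n_samples, size=n_mod, replace=False)
        response[mod_idx] = "Moderate"

    # scaffold curated network: planted + response edges, ER background on
    # pairs not already planted
    network = InteractionNetwork()
    for g in genes:
        network.add_node(g)
    for edge, _ in planted_edges:
        network.add_edge(*edge, {"planted"})
    network.add_edge(*response_pair, {"planted"})
    existing = {e for e, _ in planted_edges} | {response_pair}
    n_bg = 0
    while n_bg < config.n_background_edges:
        i, j = rng.choice(config.n_genes, size=2, replace=False)
        edge = canonical_edge(genes[int(i)], genes[int(j)])
        if edge in existing:
            continue
        network.add_edge(*edge, {"background"})
        existing.add(edge)
        n_bg += 1

    # gene sets: the planted module plus random decoys
    sets = GeneSetCollection()
    planted_genes = sorted({g for e, _ in planted_edges for g in e} | set(response_pair))
    sets.add("planted_module", "genes of planted edges", planted_genes)
    for s in range(5):
        members = rng.choice(config.n_genes, size=min(10, config.n_genes // 2), replace=False)
        sets.add(f"random_set_{s + 1}", "decoy", sorted(genes[int(i)] for i in members))

    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=sample_ids))
    annot = SampleAnnotation(
        pd.DataFrame(
            {"subgroup": groups, "response": response, "age": age}, index=sample_ids
        )
    )
    truth = SimulationTruth(
        planted_edges=planted_edges,
        planted_response_pair=response_pair,
        response_effect=config.response_effect,
        seed=config.seed,
    )
    # planted edges must exist in the emitted network
    assert all(canonical_edge(*e) in network.edges for e, _ in planted_edges)
    return expr, annot, network, sets, truth


FIXTURE_SEED = 20220711


def fixture_config() -> SimulationConfig:
    """Configuration of the small bundled toy study."""
    return SimulationConfig(
        n_genes=40,
        group_sizes={"alpha": 16, "beta": 14},
        n_planted_edges=3,
        slope_per_group={"alpha": 1.0, "beta": 0.0},
        noise_sd=0.5,
        response_effect=2.0,
        n_background_edges=40,
        seed=FIXTURE_SEED,
    )


def fixture_small(
    out_dir: str | Path | None = None,
) -> tuple[ExpressionMatrix, SampleAnnotation, InteractionNetwork, GeneSetCollection, SimulationTruth]:
    """Deterministic 40-gene x 30-sample toy study for docs and smoke tests.

    With ``out_dir`` the four input files are written in their standard
    formats (expression.tsv, annotation.csv, interactions.sif, sets.gmt).
    """
    study = simulate_study(fixture_config())
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_study(study, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated study's four input files to ``out_dir``."""
    expr, annot, network, sets, _ = study
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "annotation": out / "annotation.csv",
        "interactions": out / "interactions.sif",
        "gene_sets": out / "sets.gmt",
    }
    write_expression(expr, paths["expression"])
    df = annot.frame.copy()
    df.index.name = "sample_id"
    df.to_csv(paths["annotation"])
    write_interactions(network, paths["interactions"])
    write_gmt(sets, paths["gene_sets"])
    return paths


def null_config(**overrides) -> SimulationConfig:
    """A configuration with no planted slope differences (all groups alike)."""
    cfg = SimulationConfig(**overrides)
    cfg = replace(cfg, slope_per_group={g: 1.0 for g in cfg.group_sizes})
    return cfg
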