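"""Simulation experiments validating the pipeline's statistical behavior.

Each experiment regenerates synthetic studies from scratch, runs the
relevant pipeline stage, and summarizes an operating characteristic:

* type-I error of the subgroup x gene interaction test under the null
* false-discovery proportion of a BH-thresholded scan of one planted and
  many null edges
* detection power and slope-difference recovery for a planted
  differential edge at cohort-scale group sizes
* ranking of a planted predictive pair among null pairs by in-sample AUC,
  and the AUC gain contributed by the ratio term

All experiments are deterministic given a base seed; per-replicate seeds
are derived from it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diff_interaction import scan_network, test_edge
from .io_formats import ExpressionMatrix, SampleAnnotation
from .network_core import InteractionNetwork, canonical_edge
from .response_models import fit_ratio_logistic, select_response_samples
from .subgroup_networks import SpecificNetwork
from .synthetic_data import SimulationConfig, simulate_study

_MOD = 2**31


def _child_seed(seed: int, tag: int, r: int) -> int:
    return (seed * 1_000_003 + tag * 7919 + r) % _MOD


def interaction_type_i_error(
    n_replicates: int = 500,
    n_per_group: int = 200,
    slope: float = 1.0,
    noise_sd: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of null replicates with interaction p < alpha.

    Two equal groups share the same linear relation (identical slope), so
    the group x gene interaction is null and the rejection rate estimates
    the test's type-I error.
    """
    rng = np.random.default_rng(_child_seed(seed, 1, 0))
    n = 2 * n_per_group
    samples = [f"s{i}" for i in range(n)]
    annot = SampleAnnotation(
        pd.DataFrame({"subgroup": ["a"] * n_per_group + ["b"] * n_per_group}, index=samples)
    )
    hits = 0
    for _ in range(n_replicates):
        x = rng.normal(5.0, 1.0, n)
        y = 1.0 + slope * x + rng.normal(0.0, noise_sd, n)
        expr = ExpressionMatrix(
            pd.DataFrame(np.vstack([x, y]), index=["GA", "GB"], columns=samples)
        )
        hits += test_edge(expr, annot, ("GA", "GB")).p_raw < alpha
    return hits / n_replicates


def edge_fdr_experiment(
    n_replicates: int = 100,
    n_null_edges: int = 99,
    q: float = 0.05,
    seed: int = 0,
) -> float:
    """Mean false-discovery proportion over scans of 1 planted + null edges.

    Uses the generator's default three-subgroup cohort (49/18/16) with one
    differential planted edge; every other scanned edge links independent
    genes.  Discoveries are edges with BH-adjusted p < q.
    """
    fdps = []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=2 * n_null_edges + 4,
            n_planted_edges=1,
            n_background_edges=n_null_edges - 1,  # + the response-pair edge
            seed=_child_seed(seed, 2, r),
        )
        expr, annot, net, _, truth = simulate_study(cfg)
        results = scan_network(SpecificNetwork("all", net), expr, annot)
        planted = canonical_edge(*truth.planted_edges[0][0])
        discoveries = [x for x in results if x.p_adjusted < q]
        false = [x for x in discoveries if (x.gene_a, x.gene_b) != planted]
        fdps.append(len(false) / max(1, len(discoveries)))
    return float(np.mean(fdps))


def planted_edge_power(
    n_replicates: int = 200,
    group_sizes: tuple[int, int] = (49, 18),
    slope_difference: float = 1.0,
    noise_sd: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, float]:
    """Detection power and recovery for one planted differential edge.

    Returns the fraction of replicates with adjusted p < alpha (``power``)
    and the fraction whose estimated slope difference lies within 2
    standard errors of the truth (``recovery_2se``).
    """
    detected = recovered = 0
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=6,
            group_sizes={"a": group_sizes[0], "b": group_sizes[1]},
            slope_per_group={"a": 0.0, "b": slope_difference},
            n_planted_edges=1,
            noise_sd=noise_sd,
            n_background_edges=0,
            seed=_child_seed(seed, 3, r),
        )
        expr, annot, _, _, truth = simulate_study(cfg)
        edge = truth.planted_edges[0][0]
        net = InteractionNetwork()
        net.add_edge(*edge, {"planted"})
        res = scan_network(SpecificNetwork("planted", net), expr, annot)[0]
        detected += res.p_adjusted < alpha
        inter = next(t for t in res.fit.term_names if ":" in t)
        diff = abs(res.per_group_slope["b"] - res.per_group_slope["a"])
        recovered += abs(diff - slope_difference) < 2 * res.fit.standard_errors[inter]
    return {
        "power": detected / n_replicates,
        "recovery_2se": recovered / n_replicates,
    }


def response_pair_ranking(
    n_replicates: int = 100,
    n_null_pairs: int = 30,
    response_effect: float = 2.0,
    seed: int = 0,
) -> dict[str, float]:
    """Rank of a planted predictive pair among null pairs by in-sample AUC.

    Returns the fraction of replicates where the planted pair ranks first
    (``frac_first``) and the mean AUC gain of the planted pair's ratio
    term (``mean_auc_gain``).
    """
    first = 0
    gains = []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=2 * n_null_pairs + 10,
            n_planted_edges=0,
            n_background_edges=n_null_pairs,
            response_effect=response_effect,
            seed=_child_seed(seed, 4, r),
        )
        expr, annot, net, _, truth = simulate_study(cfg)
        binary = select_response_samples(annot)
        planted = canonical_edge(*truth.planted_response_pair)
        null_pairs = [e for e in sorted(net.edges) if e != planted][:n_null_pairs]
        aucs = []
        for a, b in [planted] + null_pairs:
            model = fit_ratio_logistic(expr, binary, a, b, covariates=["age"])
            aucs.append(model.auc_with)
            if (a, b) == planted:
                gains.append(model.auc_with - model.auc_without)
        first += int(np.argmax(aucs) == 0)
    return {
        "frac_first": first / n_replicates,
        "mean_auc_gain": float(np.mean(gains)),
    }


def ratio_auc_gain(
    n_replicates: int = 200,
    response_effect: float = 2.0,
    seed: int = 0,
) -> float:
    """Mean in-sample AUC gain of the ratio term for the planted pair."""
    gains = []
    for r in range(n_replicates):
        cfg = SimulationConfig(
            n_genes=10,
            n_planted_edges=0,
            n_background_edges=2,
            response_effect=response_effect,
            seed=_child_seed(seed, 5, r),
        )
        expr, annot, _, _, truth = simulate_study(cfg)
        binary = select_response_samples(annot)
        a, b = truth.planted_response_pair
        model = fit_ratio_logistic(expr, binary, a, b, covariates=["age"])
        gains.append(model.auc_with - model.auc_without)
    return float(np.mean(gains))
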