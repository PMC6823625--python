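"""Shared fixtures: tiny hand-built networks and one session-scoped simulated study."""

from __future__ import annotations

import numpy as np
import pytest

import edgesmooth as es


@pytest.fixture()
def triangle() -> es.PPINetwork:
    """Three proteins, three edges with distinct weights."""
    return es.PPINetwork.from_edge_list(
        [("A", "B", 0.5), ("B", "C", 0.7), ("C", "A", 0.9)]
    )


@pytest.fixture()
def single_edge() -> es.PPINetwork:
    return es.PPINetwork.from_edge_list([("A", "B", 0.64)])


@pytest.fixture(scope="session")
def sim_cfg() -> es.SimConfig:
    """The study conditions: 500-gene scale-free network, 200-patient cohort."""
    return es.SimConfig(seed=1)


@pytest.fixture(scope="session")
def study(sim_cfg: es.SimConfig) -> dict:
    """End-to-end simulated study shared across test modules.

    Network → cohort → augmentation → propagation → ranking, plus the planted
    driver edges, driver-linked survival, and the synthetic LBS catalog.
    """
    net = es.generate_network(sim_cfg)
    cohort = es.generate_cohort(net, sim_cfg)
    aug = es.augment_network(net, "sqrt")
    scores = es.propagate_cohort(aug, cohort, es.PropagationConfig())
    drivers = es.driver_edges(net, sim_cfg)
    edge_df = scores.edge_scores()
    driver_scores = edge_df[drivers].mean(axis=1)
    clinical = es.generate_survival(driver_scores, sim_cfg)
    catalog, lbs_by_patient = es.generate_lbs_catalog(cohort, sim_cfg)
    return {
        "cfg": sim_cfg,
        "net": net,
        "cohort": cohort,
        "aug": aug,
        "scores": scores,
        "drivers": drivers,
        "edge_df": edge_df,
        "clinical": clinical,
        "catalog": catalog,
        "lbs_by_patient": lbs_by_patient,
        "mutations_by_patient": {s: cohort.mutated_genes(s) for s in cohort.samples},
        "ranking": es.aggregate_decile(scores),
    }


def random_weighted_network(n_nodes: int, n_edges: int, seed: int) -> es.PPINetwork:
    """Small uniform random network helper used by several property tests."""
    from edgesmooth.simulate import generate_gnm_network

    return generate_gnm_network(n_nodes, n_edges, seed)


def random_simple_path(net: es.PPINetwork, rng: np.random.Generator, max_len: int = 8) -> list[str]:
    """A random self-avoiding walk in the original network (possibly length 1)."""
    node = net.nodes[rng.integers(net.n_nodes)]
    path = [node]
    for _ in range(max_len - 1):
        nbrs = sorted(net.adjacency(path[-1]) - set(path))
        if not nbrs:
            break
        path.append(nbrs[rng.integers(len(nbrs))])
    return path
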