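"""Deterministic synthetic fixtures: network, cohort, survival, LBS catalog.

Every generator is a pure function of a :class:`SimConfig` (seed mandatory),
so the whole pipeline is testable end-to-end without downloads.  The
emulated regime mirrors the study design the method targets: a scale-free
(preferential-attachment) interaction network with confidence-like Beta
weights, a sparse binary somatic-mutation matrix in which genes incident to
a planted set of "driver" edges are mutated at an elevated rate,
exponential survival whose hazard increases with the patient's driver-edge
scores, and an LBS catalog covering a configured fraction of each patient's
mutated genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .network import ClinicalTable, LBSCatalog, MutationMatrix, PPINetwork

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    n_nodes, attachment
        Size and preferential-attachment parameter of the scale-free network.
    weight_a, weight_b
        Beta(a, b) edge-confidence distribution on [0, 1].
    n_patients
        Cohort size.
    mutation_rate
        Background per-gene per-patient mutation probability (sparse: a few
        dozen mutated genes per patient at the default network size).
    n_driver_edges, driver_mutation_rate
        Number of planted driver edges and the elevated mutation probability
        of their endpoint genes.
    survival_effect
        Log-hazard slope on the (standardized) driver-edge score; positive
        values make high-scoring patients die earlier.
    baseline_hazard
        Exponential baseline event rate per day.
    censoring_fraction
        Probability that a patient's follow-up is cut short (uniformly within
        their survival time), independent of the covariate.
    lbs_fraction
        Fraction of each patient's mutated genes annotated with a synthetic
        ligand-binding-site substitution.
    seed
        Base seed; every generator derives its own independent stream.
    """

    n_nodes: int = 500
    attachment: int = 2
    weight_a: float = 2.0
    weight_b: float = 2.0
    n_patients: int = 200
    mutation_rate: float = 0.02
    n_driver_edges: int = 10
    driver_mutation_rate: float = 0.25
    survival_effect: float = 2.0
    baseline_hazard: float = 1.0 / 1000.0
    censoring_fraction: float = 0.3
    lbs_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "driver_mutation_rate", "censoring_fraction", "lbs_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if self.n_patients < 1:
            raise ValueError("need at least 1 patient")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, stream: str) -> np.random.Generator:
        """Named independent random stream derived from the base seed."""
        return np.random.default_rng([self.seed, abs(hash_stream(stream))])


def hash_stream(name: str) -> int:
    """Stable (process-independent) 31-bit hash of a stream name."""
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def _gene_name(i: int) -> str:
    return f"G{i:05d}"


def generate_network(cfg: SimConfig) -> PPINetwork:
    """Scale-free weighted network: Barabási–Albert topology, Beta weights.

    Preferential attachment yields a connected graph with a heavy-tailed
    degree distribution; weights are i.i.d. Beta(weight_a, weight_b) mimicking
    interaction confidence scores.
    """
    rng = cfg.rng("network")
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.attachment, seed=int(rng.integers(2**31)))
    weights = rng.beta(cfg.weight_a, cfg.weight_b, size=g.number_of_edges())
    # keep weights off the exact {0, 1} endpoints
    weights = np.clip(weights, 1e-9, 1.0 - 1e-9)
    triples = [
        (_gene_name(u), _gene_name(v), float(w))
        for (u, v), w in zip(sorted(tuple(sorted(e)) for e in g.edges()), weights)
    ]
    return PPINetwork.from_edge_list(triples)


def generate_gnm_network(n_nodes: int, n_edges: int, seed: int = 0) -> PPINetwork:
    """Uniform random G(n, m) network with uniform weights, at database scale.

    Pairs are drawn vectorially and deduplicated, so millions of edges build
    in seconds; used to exercise the augmentation size law at the scale of
    real interaction databases.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"cannot place {n_edges} edges on {n_nodes} nodes")
    rng = np.random.default_rng(seed)
    packed = np.empty(0, dtype=np.int64)
    while packed.size < n_edges:
        need = int((n_edges - packed.size) * 1.2) + 16
        u = rng.integers(0, n_nodes, size=need, dtype=np.int64)
        v = rng.integers(0, n_nodes, size=need, dtype=np.int64)
        keep = u != v
        lo = np.minimum(u[keep], v[keep])
        hi = np.maximum(u[keep], v[keep])
        merged = np.sort(np.concatenate([packed, lo * n_nodes + hi]))
        packed = merged[np.concatenate(([True], merged[1:] != merged[:-1]))]
    if packed.size > n_edges:  # drop a uniform subset of the surplus
        drop = rng.choice(packed.size, size=packed.size - n_edges, replace=False)
        packed = np.delete(packed, drop)
    edges = np.column_stack([packed // n_nodes, packed % n_nodes])
    weights = rng.random(n_edges)
    # zero-padded names keep index order == lexicographic canonical order
    width = len(str(n_nodes - 1))
    nodes = [f"G{i:0{width}d}" for i in range(n_nodes)]
    return PPINetwork(nodes, edges, weights)


def driver_edges(net: PPINetwork, cfg: SimConfig) -> list[tuple[str, str]]:
    """The planted driver edges: a seed-reproducible without-replacement draw."""
    rng = cfg.rng("drivers")
    n = min(cfg.n_driver_edges, net.n_edges)
    idx = np.sort(rng.choice(net.n_edges, size=n, replace=False))
    keys = net.edge_keys()
    return [keys[i] for i in idx]


def generate_cohort(net: PPINetwork, cfg: SimConfig) -> MutationMatrix:
    """Sparse binary mutation matrix over the network's genes.

    Background genes mutate independently at ``mutation_rate``; genes incident
    to a driver edge mutate at ``driver_mutation_rate``, planting the signal
    the pipeline is supposed to recover.
    """
    rng = cfg.rng("cohort")
    genes = net.nodes
    rates = np.full(len(genes), cfg.mutation_rate)
    for u, v in driver_edges(net, cfg):
        rates[net._index[u]] = cfg.driver_mutation_rate
        rates[net._index[v]] = cfg.driver_mutation_rate
    m = (rng.random((cfg.n_patients, len(genes))) < rates).astype(np.int8)
    samples = [f"P{i:04d}" for i in range(cfg.n_patients)]
    return MutationMatrix(pd.DataFrame(m, index=pd.Index(samples, name="sample"), columns=genes))


def generate_survival(driver_scores: pd.Series | np.ndarray, cfg: SimConfig) -> ClinicalTable:
    """Exponential survival with hazard ∝ exp(effect × standardized score).

    ``driver_scores`` holds one value per patient (typically the mean
    propagated score of the planted driver edges).  Scores are standardized
    so ``survival_effect`` is a per-SD log-hazard ratio; censoring truncates
    a ``censoring_fraction`` of follow-ups uniformly, independent of the
    covariate.
    """
    if isinstance(driver_scores, pd.Series):
        samples = list(driver_scores.index)
        x = driver_scores.to_numpy(dtype=float)
    else:
        x = np.asarray(driver_scores, dtype=float)
        samples = [f"P{i:04d}" for i in range(x.size)]
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    rng = cfg.rng("survival")
    hazard = cfg.baseline_hazard * np.exp(cfg.survival_effect * z)
    times = rng.exponential(1.0 / hazard)
    censored = rng.random(x.size) < cfg.censoring_fraction
    observed = np.where(censored, times * rng.random(x.size), times)
    observed = np.maximum(observed, 1e-6)  # strictly positive follow-up
    df = pd.DataFrame(
        {"time_days": observed, "event": (~censored).astype(int)},
        index=pd.Index(samples, name="sample"),
    )
    return ClinicalTable(df)


def generate_lbs_catalog(
    mutations: MutationMatrix, cfg: SimConfig
) -> tuple[LBSCatalog, dict[str, set[str]]]:
    """Synthetic LBS annotations for a fraction of each patient's mutated genes.

    Returns the catalog (gene → substitution strings like "F293L") plus the
    per-patient LBS gene sets actually drawn, both reproducible per seed.
    """
    rng = cfg.rng("lbs")
    entries: dict[str, set[str]] = {}
    per_patient: dict[str, set[str]] = {}
    for sample in mutations.samples:
        genes = sorted(mutations.mutated_genes(sample))
        k = int(round(cfg.lbs_fraction * len(genes)))
        if cfg.lbs_fraction == 1.0:
            k = len(genes)
        chosen = (
            list(rng.choice(genes, size=k, replace=False)) if 0 < k <= len(genes) else []
        )
        per_patient[sample] = set(chosen)
        for g in chosen:
            aa_from, aa_to = rng.choice(list(_AA), size=2)
            pos = int(rng.integers(1, 1000))
            entries.setdefault(g, set()).add(f"{aa_from}{pos}{aa_to}")
    return LBSCatalog(entries), per_patient


def with_seed(cfg: SimConfig, seed: int) -> SimConfig:
    """A copy of the configuration with a different base seed."""
    return replace(cfg, seed=seed)
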