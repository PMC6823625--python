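"""Restart-style network smoothing over the augmented network.

Solves the fixed point

    F = α · S · F + (1 − α) · Y,

where S is the degree-normalized weight operator of G' and Y is the binary
somatic-mutation prior (1 on mutated genes, 0 elsewhere, always 0 on dummy
nodes).  Because dummy nodes carry a propagated value, the fixed point scores
every interaction as well as every protein.  With the symmetric normalization
S = D^{-1/2} W' D^{-1/2} (spectral radius ≤ 1) the power iteration converges
geometrically for any α < 1, and the iterative solution agrees with the
direct linear solve (1 − α)(I − αS)^{-1} Y.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .augment import AugmentedNetwork
from .network import MutationMatrix

logger = logging.getLogger("edgesmooth")


class ConvergenceError(RuntimeError):
    """Smoothing failed to reach the tolerance within the iteration budget."""

    def __init__(self, residual: float, max_iter: int) -> None:
        super().__init__(
            f"propagation did not converge within {max_iter} iterations "
            f"(max-norm residual {residual:.3e})"
        )
        self.residual = residual
        self.max_iter = max_iter


@dataclass(frozen=True)
class PropagationConfig:
    """Tunable smoothing parameters.

    alpha
        Mixing weight of the network term; 1 − alpha is the restart weight on
        the prior.  0 ≤ alpha < 1 (alpha = 0 returns the prior unchanged).
    tol
        Max-norm convergence tolerance on successive iterates.
    max_iter
        Iteration budget before :class:`ConvergenceError`.
    scheme
        Half-edge weight scheme expected on the augmented network
        ("sqrt" preserves path reliability, "half" does not).
    normalize_prior
        If True, rescale a nonzero prior to sum to 1 before smoothing
        (off by default: the prior is the binary mutation indicator).
    """

    alpha: float = 0.8
    tol: float = 1e-6
    max_iter: int = 1000
    scheme: Literal["sqrt", "half"] = "sqrt"
    normalize_prior: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be ≥ 1")
        if self.scheme not in ("sqrt", "half"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def build_prior(aug: AugmentedNetwork, mutated_genes: Iterable[str]) -> np.ndarray:
    """Binary prior Y over V': 1 for mutated genes present in the network.

    Dummy nodes always start at 0; mutated genes absent from the network are
    ignored with a logged count (they contribute nothing to propagation).
    """
    y = np.zeros(aug.n_nodes, dtype=np.float64)
    index = aug.source._index
    missing = 0
    for g in mutated_genes:
        i = index.get(g)
        if i is None:
            missing += 1
        else:
            y[i] = 1.0
    if missing:
        logger.warning("build_prior: %d mutated genes absent from the network", missing)
    return y


def normalized_operator(aug: AugmentedNetwork) -> sp.csr_array:
    """S = D^{-1/2} W' D^{-1/2} with D the weighted-degree diagonal of G'.

    Isolated original nodes (zero degree) get a zero row/column, so their
    fixed point is (1 − α) Y; dummy nodes always have degree 2 > 0.
    """
    w = aug.sparse_weights()
    deg = np.asarray(w.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    d = sp.diags_array(inv_sqrt)
    return (d @ w @ d).tocsr()


def _iterate(s: sp.csr_array, y: np.ndarray, cfg: PropagationConfig) -> np.ndarray:
    if not y.any():
        return np.zeros_like(y)  # zero prior is already the fixed point
    if cfg.normalize_prior:
        y = y / y.sum()
    if cfg.alpha == 0.0:
        return y.copy()
    f = y.copy()
    restart = (1.0 - cfg.alpha) * y
    residual = np.inf
    for _ in range(cfg.max_iter):
        f_next = cfg.alpha * (s @ f) + restart
        residual = float(np.max(np.abs(f_next - f)))
        f = f_next
        if residual < cfg.tol:
            return f
    raise ConvergenceError(residual, cfg.max_iter)


def smooth(
    aug: AugmentedNetwork,
    prior: np.ndarray,
    cfg: PropagationConfig = PropagationConfig(),
) -> np.ndarray:
    """Propagate one prior vector to its smoothed fixed point over V'.

    Returns the score vector m aligned with ``aug.node_names()`` (original
    nodes first, then dummies).  Scores arise purely from the converged
    iteration — no post-hoc clipping is applied.
    """
    if aug.scheme != cfg.scheme:
        raise ValueError(
            f"augmented network uses scheme {aug.scheme!r} but config expects {cfg.scheme!r}"
        )
    prior = np.asarray(prior, dtype=np.float64)
    if prior.shape != (aug.n_nodes,):
        raise ValueError(f"prior has shape {prior.shape}, expected ({aug.n_nodes},)")
    if prior.min() < 0.0 or prior.max() > 1.0:
        raise ValueError("prior values must lie in [0, 1]")
    if prior[aug.n_original:].any():
        raise ValueError("prior must be zero on dummy nodes")
    return _iterate(normalized_operator(aug), prior, cfg)


@dataclass
class ScoreMatrix:
    """Propagated scores for a cohort: samples × (original nodes ∪ dummy nodes).

    Row i is exactly ``smooth`` applied to sample i's mutation prior; the
    edge sub-matrix is addressable by canonical edge keys.
    """

    aug: AugmentedNetwork
    samples: list[str]
    values: np.ndarray  # (n_samples, |V'|)
    _node_names: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.samples), self.aug.n_nodes):
            raise ValueError("score matrix shape mismatch")
        if not self._node_names:
            self._node_names = self.aug.node_names()

    @property
    def node_names(self) -> list[str]:
        return self._node_names

    @property
    def edge_keys(self) -> list[tuple[str, str]]:
        return self.aug.source.edge_keys()

    def node_scores(self) -> pd.DataFrame:
        """Samples × original-protein scores."""
        return pd.DataFrame(
            self.values[:, : self.aug.n_original],
            index=self.samples,
            columns=self.aug.original_nodes,
        )

    def edge_scores(self) -> pd.DataFrame:
        """Samples × interaction scores, columns keyed by canonical edge key."""
        return pd.DataFrame(
            self.values[:, self.aug.n_original:],
            index=self.samples,
            columns=pd.Index(self.edge_keys, tupleize_cols=False),
        )

    def edge_values(self) -> np.ndarray:
        """(n_samples, |E|) view of the dummy-node block."""
        return self.values[:, self.aug.n_original:]

    def sample_row(self, sample: str) -> np.ndarray:
        return self.values[self.samples.index(sample)]


def propagate_cohort(
    aug: AugmentedNetwork,
    mutations: MutationMatrix,
    cfg: PropagationConfig = PropagationConfig(),
) -> ScoreMatrix:
    """Smooth every sample's mutation prior over G'.

    The normalized operator is built once and reused across samples; each row
    is numerically identical to a one-off :func:`smooth` call for that sample.
    Row order follows the mutation matrix.
    """
    if not mutations.samples:
        raise ValueError("mutation matrix has no samples")
    s = normalized_operator(aug)
    index = aug.source._index
    gene_cols: list[tuple[int, int]] = []  # (column in M, node index in V')
    for j, gene in enumerate(mutations.genes):
        i = index.get(gene)
        if i is not None:
            gene_cols.append((j, i))
    n_missing = len(mutations.genes) - len(gene_cols)
    if n_missing:
        logger.warning(
            "propagate_cohort: %d of %d mutated genes absent from the network",
            n_missing,
            len(mutations.genes),
        )
    m_arr = mutations.data.to_numpy()
    out = np.zeros((len(mutations.samples), aug.n_nodes))
    for r in range(m_arr.shape[0]):
        y = np.zeros(aug.n_nodes)
        for j, i in gene_cols:
            if m_arr[r, j]:
                y[i] = 1.0
        out[r] = _iterate(s, y, cfg)
    return ScoreMatrix(aug, list(mutations.samples), out)


# ---------------------------------------------------------------------------
# writers / config IO
# ---------------------------------------------------------------------------


def write_scores_wide(scores: ScoreMatrix, path: str | Path) -> None:
    """Wide TSV: one row per sample, one column per node/dummy."""
    df = pd.DataFrame(scores.values, index=scores.samples, columns=scores.node_names)
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.10g")

def write_scores_long(scores: ScoreMatrix, path: str | Path, threshold: float = 0.0) -> None:
    """Long/sparse TSV (sample, node-or-edge key, score), skipping scores ≤ threshold."""
    names = scores.node_names
    with open(path, "w") as fh:
        fh.write("sample\tnode\tscore\n")
        for r, sample in enumerate(scores.samples):
            row = scores.values[r]
            for c in np.flatnonzero(row > threshold):
                fh.write(f"{sample}\t{names[c]}\t{row[c]:.10g}\n")


def write_config(cfg: PropagationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"alpha={cfg.alpha!r}\n")
        fh.write(f"tol={cfg.tol!r}\n")
        fh.write(f"max_iter={cfg.max_iter}\n")
        fh.write(f"scheme={cfg.scheme}\n")
        fh.write(f"normalize_prior={cfg.normalize_prior}\n")


def read_config(path: str | Path) -> PropagationConfig:
    """Parse a key=value config file mirroring :class:`PropagationConfig`."""
    kwargs: dict[str, object] = {}
    casts = {
        "alpha": float,
        "tol": float,
        "max_iter": int,
        "scheme": str,
        "normalize_prior": lambda s: s.strip().lower() in {"1", "true", "yes"},
    }
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{line_no}: expected key=value")
            key, _, raw = line.partition("=")
            key = key.strip()
            if key not in casts:
                raise ValueError(f"{path}:{line_no}: unknown key {key!r}")
            kwargs[key] = casts[key](raw.strip())
    return PropagationConfig(**kwargs)  # type: ignore[arg-type]
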