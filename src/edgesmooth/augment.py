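"""Graph augmentation: one dummy node per interaction edge.

Each edge {u, v} of the original network G is subdivided by a dummy node
``uv`` sitting in its middle, so that network smoothing assigns a score to
the interaction itself.  The two resulting half-edges carry weight
w'(u, uv) = w'(uv, v) = √w(u, v) by default, which preserves the reliability
(product of weights) of every path between original nodes; the w/2
alternative is kept for comparison and does not preserve reliability.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp

from .network import PPINetwork, canonical_edge_key

WeightScheme = Literal["sqrt", "half"]

#: separator used to derive a dummy-node identifier from a canonical edge key
DUMMY_SEP = "|"


def dummy_name(u: str, v: str) -> str:
    """Deterministic dummy-node identifier for the edge {u, v}."""
    a, b = canonical_edge_key(u, v)
    return f"{a}{DUMMY_SEP}{b}"


class AugmentedNetwork:
    """The adjusted network G' = (V', E', w').

    V' = V ∪ {uv : {u, v} ∈ E}; E' replaces every original edge by the two
    half-edges {u, uv} and {uv, v}, so |V'| = |V| + |E| and |E'| = 2|E|, and
    every dummy node has degree exactly 2.

    The container is array-backed: dummy node *i* corresponds to the *i*-th
    edge of the source network's canonical edge order, and dummy identifiers
    ("u|v") are derived from canonical keys on demand, which keeps
    construction O(|E|) even for millions of interactions.
    """

    def __init__(self, source: PPINetwork, scheme: WeightScheme = "sqrt") -> None:
        if scheme not in ("sqrt", "half"):
            raise ValueError(f"unknown weight scheme {scheme!r}")
        self.source = source
        self.scheme: WeightScheme = scheme
        self.edge_indices = source.edge_indices  # (m, 2) original-node index pairs
        if scheme == "sqrt":
            self.half_weights = np.sqrt(source.weights)
        else:
            self.half_weights = source.weights / 2.0
        self._dummy_lookup: dict[str, int] | None = None
        self._key_lookup: dict[tuple[str, str], int] | None = None

    # -- size law -----------------------------------------------------------

    @property
    def n_original(self) -> int:
        return self.source.n_nodes

    @property
    def n_dummies(self) -> int:
        return self.source.n_edges

    @property
    def n_nodes(self) -> int:
        """|V'| = |V| + |E|."""
        return self.n_original + self.n_dummies

    @property
    def n_edges(self) -> int:
        """|E'| = 2 |E|."""
        return 2 * self.n_dummies

    # -- node naming --------------------------------------------------------

    @property
    def original_nodes(self) -> list[str]:
        return self.source.nodes

    def dummy_names(self) -> list[str]:
        """All dummy identifiers in canonical edge order (materialized on demand)."""
        return [f"{u}{DUMMY_SEP}{v}" for u, v in self.source.edge_keys()]

    def node_names(self) -> list[str]:
        """V' in propagation order: original nodes first, then dummies."""
        return self.original_nodes + self.dummy_names()

    def is_dummy(self, node: str) -> bool:
        return node not in self.source and node in self._dummies()

    def _dummies(self) -> dict[str, int]:
        if self._dummy_lookup is None:
            self._dummy_lookup = {name: i for i, name in enumerate(self.dummy_names())}
        return self._dummy_lookup

    def _keys(self) -> dict[tuple[str, str], int]:
        if self._key_lookup is None:
            self._key_lookup = {k: i for i, k in enumerate(self.source.edge_keys())}
        return self._key_lookup

    # -- dummy ↔ edge bijection ---------------------------------------------

    def edge_of_dummy(self, dummy: str) -> tuple[str, str]:
        """Canonical edge key represented by ``dummy`` (inverse of :meth:`dummy_of_edge`)."""
        try:
            i = self._dummies()[dummy]
        except KeyError:
            raise KeyError(f"{dummy!r} is not a dummy node of this network") from None
        return self.source.edge_keys()[i]

    def dummy_of_edge(self, u: str, v: str | None = None) -> str:
        """Dummy-node identifier for the edge {u, v} (accepts a key tuple too)."""
        if v is None:
            u, v = u  # type: ignore[misc]
        key = canonical_edge_key(u, v)
        if key not in self._keys():
            raise KeyError(f"no edge {key} in the source network")
        return f"{key[0]}{DUMMY_SEP}{key[1]}"

    # -- weights ------------------------------------------------------------

    def get_weight(self, a: str, b: str) -> float:
        """Weight of the half-edge {a, b}; exactly one endpoint must be a dummy."""
        if self.is_dummy(a) and not self.is_dummy(b):
            a, b = b, a
        if self.is_dummy(b) and not self.is_dummy(a):
            i = self._dummies()[b]
            u, v = self.source.edge_keys()[i]
            if a in (u, v):
                return float(self.half_weights[i])
        raise KeyError(f"no half-edge between {a!r} and {b!r}")

    def has_edge(self, a: str, b: str) -> bool:
        try:
            self.get_weight(a, b)
            return True
        except KeyError:
            return False

    def sparse_weights(self) -> sp.csr_array:
        """Symmetric sparse W' over V' (original nodes first, then dummies)."""
        n, m = self.n_original, self.n_dummies
        dummy_idx = np.arange(n, n + m)
        rows = np.concatenate([self.edge_indices[:, 0], self.edge_indices[:, 1]])
        cols = np.concatenate([dummy_idx, dummy_idx])
        vals = np.concatenate([self.half_weights, self.half_weights])
        w = sp.coo_array(
            (np.concatenate([vals, vals]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
            shape=(n + m, n + m),
        )
        return w.tocsr()

    def __repr__(self) -> str:
        return (
            f"AugmentedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges}, "
            f"scheme={self.scheme!r})"
        )


def augment_network(net: PPINetwork, scheme: WeightScheme = "sqrt") -> AugmentedNetwork:
    """Build the adjusted network G' with a dummy node per edge.

    With ``scheme="sqrt"`` the half-edges weigh √w, so any path between
    original nodes keeps its reliability; ``scheme="half"`` uses w/2.
    """
    return AugmentedNetwork(net, scheme)


def path_reliability(net: PPINetwork | AugmentedNetwork, path: Sequence[str]) -> float:
    """Reliability r(p) = ∏ w(u, v) along a node sequence; empty path → 1.

    Raises
    ------
    KeyError
        If a consecutive pair is not adjacent in the network.
    """
    r = 1.0
    for a, b in zip(path, path[1:]):
        r *= net.get_weight(a, b)
    return r


def augmented_path(aug: AugmentedNetwork, path: Sequence[str]) -> list[str]:
    """Lift an original-network path to G' by inserting the dummy node of each edge."""
    if not path:
        return []
    out = [path[0]]
    for a, b in zip(path, path[1:]):
        out.append(aug.dummy_of_edge(a, b))
        out.append(b)
    return out


def write_augmented(aug: AugmentedNetwork, edges_path: str | Path, map_path: str | Path) -> None:
    """Write the half-edge list and the dummy ↔ edge map as TSV."""
    keys = aug.source.edge_keys()
    with open(edges_path, "w") as fh:
        fh.write("u\tv\tweight\n")
        for (u, v), w in zip(keys, aug.half_weights):
            d = f"{u}{DUMMY_SEP}{v}"
            fh.write(f"{u}\t{d}\t{w!r}\n")
            fh.write(f"{d}\t{v}\t{w!r}\n")
    with open(map_path, "w") as fh:
        fh.write("dummy\tgene1\tgene2\n")
        for u, v in keys:
            fh.write(f"{u}{DUMMY_SEP}{v}\t{u}\t{v}\n")
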