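"""Domain types and readers for protein-interaction networks and cohort data.

The central container is :class:`PPINetwork`, an undirected weighted graph
G = (V, E, w) with confidence weights w ∈ [0, 1], stored in canonical
(lexicographically sorted) edge order so that every downstream artifact —
augmented networks, score matrices, rankings — is deterministic.

Cohort-side containers: :class:`MutationMatrix` (binary samples × genes),
:class:`ClinicalTable` (right-censored survival records) and
:class:`LBSCatalog` (gene → ligand-binding-site amino-acid substitutions).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("edgesmooth")

#: MAF variant classifications that set M[i, j] = 1 by default: protein-level
#: changes (missense, nonsense, frame shifts, in-frame indels).
DEFAULT_VARIANT_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
    }
)

#: One-letter amino-acid codes accepted in substitution strings such as "F293L".
_AA = "ACDEFGHIKLMNPQRSTVWY"
SUBSTITUTION_RE = re.compile(rf"^[{_AA}]\d+[{_AA}]$")


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


def canonical_edge_key(u: str, v: str) -> tuple[str, str]:
    """Return the unordered pair {u, v} as a lexicographically sorted tuple.

    The canonical key identifies an interaction independently of the order its
    endpoints were read in: ``canonical_edge_key(u, v) == canonical_edge_key(v, u)``.

    Raises
    ------
    ValueError
        If ``u == v`` (self-interactions carry no edge identity here).
    """
    if u == v:
        raise ValueError(f"self-loop ({u!r}, {u!r}) has no canonical edge key")
    return (u, v) if u < v else (v, u)


class PPINetwork:
    """Undirected weighted protein-interaction network.

    Nodes are gene/protein symbols; edges are unordered pairs with a single
    confidence weight in [0, 1].  Internally the network is array-backed
    (node index pairs + weight vector, sorted by canonical edge key), which
    keeps construction and augmentation fast at database scale; adjacency and
    per-edge lookup dictionaries are built lazily.

    Invariants: no self-loops, at most one edge per unordered pair, all
    weights in [0, 1], symmetric adjacency.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        edge_indices: np.ndarray,
        weights: np.ndarray,
        *,
        report: Mapping[str, int] | None = None,
        validate: bool = True,
    ) -> None:
        self.nodes: list[str] = list(nodes)
        self._index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        self.edge_indices = np.asarray(edge_indices, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(weights, dtype=np.float64).reshape(-1)
        #: reader bookkeeping (dropped self-loops, collapsed duplicates, ...)
        self.report: dict[str, int] = dict(report or {})
        self._edge_keys: list[tuple[str, str]] | None = None
        self._edge_lookup: dict[tuple[str, str], int] | None = None
        self._adjacency: dict[str, set[str]] | None = None
        if validate:
            self._validate()

    def _validate(self) -> None:
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node labels")
        m = self.edge_indices.shape[0]
        if self.weights.shape[0] != m:
            raise ValueError("edge/weight length mismatch")
        if m == 0:
            return
        if self.edge_indices.min() < 0 or self.edge_indices.max() >= len(self.nodes):
            raise ValueError("edge index out of range")
        if np.any(self.edge_indices[:, 0] == self.edge_indices[:, 1]):
            raise ValueError("self-loop present")
        if np.any(self.weights < 0.0) or np.any(self.weights > 1.0):
            raise ValueError("edge weight outside [0, 1]")
        # one edge per unordered pair
        lo = np.minimum(self.edge_indices[:, 0], self.edge_indices[:, 1])
        hi = np.maximum(self.edge_indices[:, 0], self.edge_indices[:, 1])
        packed = np.sort(lo * len(self.nodes) + hi)
        if m > 1 and np.any(packed[1:] == packed[:-1]):
            raise ValueError("duplicate edge between the same pair")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_edge_list(
        cls,
        triples: Iterable[tuple[str, str, float]],
        *,
        extra_nodes: Iterable[str] = (),
        report: Mapping[str, int] | None = None,
    ) -> "PPINetwork":
        """Build a network from (u, v, w) triples.

        Self-loops are dropped and duplicate unordered pairs collapsed to
        their maximum weight; both are counted in ``report``.
        """
        best: dict[tuple[str, str], float] = {}
        n_self = 0
        n_dup = 0
        node_set: set[str] = set(extra_nodes)
        for u, v, w in triples:
            node_set.add(u)
            node_set.add(v)
            if u == v:
                n_self += 1
                continue
            key = canonical_edge_key(u, v)
            if key in best:
                n_dup += 1
                best[key] = max(best[key], float(w))
            else:
                best[key] = float(w)
        nodes = sorted(node_set)
        index = {n: i for i, n in enumerate(nodes)}
        keys = sorted(best)
        edge_indices = np.array(
            [(index[a], index[b]) for a, b in keys], dtype=np.int64
        ).reshape(-1, 2)
        weights = np.array([best[k] for k in keys], dtype=np.float64)
        full_report = dict(report or {})
        full_report["self_loops_dropped"] = full_report.get("self_loops_dropped", 0) + n_self
        full_report["duplicates_collapsed"] = full_report.get("duplicates_collapsed", 0) + n_dup
        if n_self or n_dup:
            logger.info(
                "network construction: %d self-loops dropped, %d duplicate pairs collapsed",
                n_self,
                n_dup,
            )
        return cls(nodes, edge_indices, weights, report=full_report)

    @classmethod
    def from_networkx(cls, graph) -> "PPINetwork":
        """Convert a ``networkx.Graph`` whose edges carry a ``weight`` attribute."""
        return cls.from_edge_list(
            ((u, v, d.get("weight", 1.0)) for u, v, d in graph.edges(data=True)),
            extra_nodes=graph.nodes(),
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), w in zip(self.edge_keys(), self.weights):
            g.add_edge(u, v, weight=float(w))
        return g

    # -- accessors ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.edge_indices.shape[0])

    def edge_keys(self) -> list[tuple[str, str]]:
        """Canonical (sorted-pair) keys in the network's deterministic edge order."""
        if self._edge_keys is None:
            self._edge_keys = [
                canonical_edge_key(self.nodes[i], self.nodes[j])
                for i, j in self.edge_indices
            ]
        return self._edge_keys

    def _lookup(self) -> dict[tuple[str, str], int]:
        if self._edge_lookup is None:
            self._edge_lookup = {k: i for i, k in enumerate(self.edge_keys())}
        return self._edge_lookup

    def has_node(self, v: str) -> bool:
        return v in self._index

    def has_edge(self, u: str, v: str) -> bool:
        if u == v:
            return False
        return canonical_edge_key(u, v) in self._lookup()

    def get_weight(self, u: str, v: str) -> float:
        try:
            return float(self.weights[self._lookup()[canonical_edge_key(u, v)]])
        except KeyError:
            raise KeyError(f"no edge between {u!r} and {v!r}") from None

    def adjacency(self, v: str) -> set[str]:
        """Adj[v]: the set of genes adjacent to v."""
        if self._adjacency is None:
            adj: dict[str, set[str]] = {n: set() for n in self.nodes}
            for i, j in self.edge_indices:
                a, b = self.nodes[i], self.nodes[j]
                adj[a].add(b)
                adj[b].add(a)
            self._adjacency = adj
        return self._adjacency[v]

    def degrees(self) -> np.ndarray:
        """Unweighted degree per node, aligned with ``self.nodes``."""
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edge_indices[:, 0], 1)
        np.add.at(deg, self.edge_indices[:, 1], 1)
        return deg

    def __contains__(self, v: str) -> bool:
        return v in self._index

    def __repr__(self) -> str:
        return f"PPINetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


# ---------------------------------------------------------------------------
# network readers / writers
# ---------------------------------------------------------------------------


def _parse_generic_tsv(path: Path) -> Iterator[tuple[str, str, float]]:
    with open(path) as fh:
        first = True
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: expected 3 tab-separated columns")
            if first and parts[2].lower() in {"w", "weight", "confidence"}:
                first = False
                continue  # optional header
            first = False
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: bad weight {parts[2]!r}") from exc
            yield parts[0], parts[1], w


def _parse_hippie(path: Path) -> Iterator[tuple[str, str, float]]:
    # HIPPIE tab format: protein1, entrez1, protein2, entrez2, confidence, evidence
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}:{line_no}: expected ≥5 HIPPIE columns")
            if line_no == 1 and parts[4].lower() in {"confidence", "score"}:
                continue
            try:
                w = float(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: bad confidence {parts[4]!r}") from exc
            yield parts[0], parts[2], w


def _parse_string(path: Path) -> Iterator[tuple[str, str, float]]:
    # STRING protein-links: "protein1 protein2 combined_score", space-separated,
    # one header line; combined_score on a 0-1000 scale, rescaled to [0, 1].
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: expected 3 space-separated columns")
            if line_no == 1 and parts[2].lower() == "combined_score":
                continue
            try:
                score = float(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{line_no}: bad combined_score {parts[2]!r}") from exc
            yield parts[0], parts[1], score / 1000.0


_NETWORK_PARSERS = {"tsv": _parse_generic_tsv, "hippie": _parse_hippie, "string": _parse_string}


def read_ppi_network(path: str | Path, format: str = "tsv", min_weight: float = 0.0) -> PPINetwork:
    """Read a weighted PPI network in HIPPIE, STRING or generic-TSV dialect.

    Edges with weight below ``min_weight`` are excluded (STRING's downloadable
    release applies a 0.15 floor on the rescaled combined score); duplicate
    pairs keep the maximum weight and self-loops are dropped, with counts
    recorded in ``network.report``.

    Raises
    ------
    FormatError
        Unknown format, unparseable line, weight outside [0, 1] after
        rescaling, or an empty network after filtering.
    """
    if format not in _NETWORK_PARSERS:
        raise FormatError(f"unknown network format {format!r}; expected one of {sorted(_NETWORK_PARSERS)}")
    if not 0.0 <= min_weight <= 1.0:
        raise ValueError(f"min_weight must be in [0, 1], got {min_weight}")
    path = Path(path)
    n_below = 0

    def filtered() -> Iterator[tuple[str, str, float]]:
        nonlocal n_below
        for u, v, w in _NETWORK_PARSERS[format](path):
            if not 0.0 <= w <= 1.0:
                raise FormatError(f"{path}: weight {w} outside [0, 1] (after rescaling)")
            if w < min_weight:
                n_below += 1
                continue
            yield u, v, w

    net = PPINetwork.from_edge_list(filtered())
    net.report["below_min_weight"] = n_below
    if net.n_edges == 0:
        raise FormatError(f"{path}: no edges remain after filtering (min_weight={min_weight})")
    logger.info(
        "read %s network %s: %d nodes, %d edges (%d below min_weight)",
        format,
        path.name,
        net.n_nodes,
        net.n_edges,
        n_below,
    )
    return net


def write_ppi_network(net: PPINetwork, path: str | Path) -> None:
    """Write a network as generic 3-column TSV (canonical edge order)."""
    with open(path, "w") as fh:
        fh.write("u\tv\tweight\n")
        for (u, v), w in zip(net.edge_keys(), net.weights):
            fh.write(f"{u}\t{v}\t{float(w)!r}\n")


# ---------------------------------------------------------------------------
# mutation matrix
# ---------------------------------------------------------------------------


@dataclass
class MutationMatrix:
    """Binary samples × genes matrix M: M[i, j] = 1 iff gene j is mutated in sample i."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample IDs")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate gene symbols")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("mutation matrix must be binary")
        self.data = self.data.astype(np.int8)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)

    def mutated_genes(self, sample: str) -> set[str]:
        row = self.data.loc[sample]
        return set(row.index[row.to_numpy() == 1])

    def __repr__(self) -> str:
        return f"MutationMatrix({self.data.shape[0]} samples × {self.data.shape[1]} genes)"


def read_mutation_matrix(
    path: str | Path,
    included_classes: frozenset[str] | set[str] = DEFAULT_VARIANT_CLASSES,
) -> MutationMatrix:
    """Build the binary mutation matrix from a MAF-like TSV.

    Requires columns ``Tumor_Sample_Barcode``, ``Hugo_Symbol`` and
    ``Variant_Classification``.  A cell is 1 iff the sample carries at least
    one mutation of an included class in that gene; repeated hits stay 1.
    Samples whose mutations are all excluded keep an all-zero row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing MAF columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: no mutation records")
    samples = sorted(df["Tumor_Sample_Barcode"].unique())
    kept = df[df["Variant_Classification"].isin(included_classes)]
    genes = sorted(kept["Hugo_Symbol"].unique())
    matrix = pd.DataFrame(0, index=pd.Index(samples, name="sample"), columns=genes, dtype=np.int8)
    if not kept.empty:
        flags = kept.groupby(["Tumor_Sample_Barcode", "Hugo_Symbol"]).size().clip(upper=1)
        for (s, g), v in flags.items():
            matrix.loc[s, g] = v
    if matrix.shape[0] == 0:
        raise FormatError(f"{path}: zero samples after filtering")
    return MutationMatrix(matrix)


def write_mutation_matrix(m: MutationMatrix, path: str | Path) -> None:
    """Write a MAF-like TSV (one Missense_Mutation row per 1-cell) readable by
    :func:`read_mutation_matrix`.  Samples with no qualifying mutations are
    preserved via a Silent placeholder row (excluded by the default classes)."""
    with open(path, "w") as fh:
        fh.write("Tumor_Sample_Barcode\tHugo_Symbol\tVariant_Classification\n")
        arr = m.data.to_numpy()
        for i, sample in enumerate(m.samples):
            idx = np.flatnonzero(arr[i])
            if idx.size == 0:
                fh.write(f"{sample}\t_NONE_\tSilent\n")
            for j in idx:
                fh.write(f"{sample}\t{m.genes[j]}\tMissense_Mutation\n")


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------


@dataclass
class ClinicalTable:
    """Right-censored survival records: per sample a positive follow-up time in
    days and an event indicator (1 = death observed, 0 = censored)."""

    data: pd.DataFrame  # index: sample; columns: time_days (float), event (int)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample IDs in clinical table")
        if (self.data["time_days"] <= 0).any():
            raise ValueError("survival times must be strictly positive")
        if not self.data["event"].isin((0, 1)).all():
            raise ValueError("event indicator must be 0/1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def aligned(self, samples: Iterable[str]) -> pd.DataFrame:
        """Rows for the given samples, in the given order (KeyError if absent)."""
        return self.data.loc[list(samples)]


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample, time_days, event.

    Malformed rows raise :class:`FormatError` with their line numbers.
    """
    path = Path(path)
    rows: list[tuple[str, float, int]] = []
    bad: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["sample", "time_days", "event"]
        if [c.strip() for c in header[:3]] != required:
            raise FormatError(f"{path}: expected header {required}, got {header[:3]}")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            try:
                if len(parts) < 3:
                    raise ValueError("too few columns")
                t = float(parts[1])
                e = int(parts[2])
                if t <= 0:
                    raise ValueError(f"non-positive time {t}")
                if e not in (0, 1):
                    raise ValueError(f"event must be 0/1, got {e}")
            except ValueError as exc:
                bad.append(f"line {line_no}: {exc}")
                continue
            rows.append((parts[0], t, e))
    if bad:
        raise FormatError(f"{path}: malformed rows — " + "; ".join(bad))
    df = pd.DataFrame(rows, columns=["sample", "time_days", "event"]).set_index("sample")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttime_days\tevent\n")
        for sample, row in table.data.iterrows():
            fh.write(f"{sample}\t{float(row['time_days'])!r}\t{int(row['event'])}\n")


# ---------------------------------------------------------------------------
# ligand-binding-site catalog
# ---------------------------------------------------------------------------


@dataclass
class LBSCatalog:
    """Gene → set of ligand-binding-site amino-acid substitutions (e.g. "F293L")."""

    entries: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, subs in self.entries.items():
            for sub in subs:
                if not SUBSTITUTION_RE.match(sub):
                    raise ValueError(f"bad substitution {sub!r} for gene {gene}")

    @property
    def genes(self) -> set[str]:
        return set(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_lbs_catalog(path: str | Path) -> LBSCatalog:
    """Read a two-column TSV (gene, substitution) into an :class:`LBSCatalog`."""
    path = Path(path)
    entries: dict[str, set[str]] = {}
    bad: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [c.strip().lower() for c in header[:2]] != ["gene", "substitution"]:
            raise FormatError(f"{path}: expected header ['gene', 'substitution']")
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not SUBSTITUTION_RE.match(parts[1]):
                bad.append(f"line {line_no}: unparseable substitution {line!r}")
                continue
            entries.setdefault(parts[0], set()).add(parts[1])
    if bad:
        raise FormatError(f"{path}: malformed rows — " + "; ".join(bad))
    return LBSCatalog(entries)


def write_lbs_catalog(catalog: LBSCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tsubstitution\n")
        for gene in sorted(catalog.entries):
            for sub in sorted(catalog.entries[gene]):
                fh.write(f"{gene}\t{sub}\n")
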