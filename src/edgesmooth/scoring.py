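"""Cohort-level aggregation of propagated edge scores.

Per patient, the distribution over all edges is summarized by its median or
maximum; across patients, each edge is summarized by its k-th highest score
with k = ⌊n · fraction⌋ (the 80th-decile rule at fraction 0.2: an edge scores
highly overall only if it is mutation-proximal in at least 20% of patients).
The resulting ranking is fully deterministic: descending aggregate score,
ties broken by ascending canonical edge key.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .propagate import ScoreMatrix


@dataclass(frozen=True)
class EdgeRanking:
    """Deterministically ordered (edge key, aggregate score) list.

    ``fraction`` and ``k`` record the aggregation rule (k-th highest across
    the cohort's n samples, k = ⌊n · fraction⌋).
    """

    entries: tuple[tuple[tuple[str, str], float], ...]
    fraction: float
    k: int

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [e for e, _ in self.entries]

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "edge": ["|".join(e) for e in self.edges],
                "gene1": [e[0] for e in self.edges],
                "gene2": [e[1] for e in self.edges],
                "score": self.scores,
            }
        )
        df["rank"] = np.arange(1, len(df) + 1)
        return df


def collapse_per_patient(scores: ScoreMatrix, stat: Literal["median", "max"] = "median") -> pd.Series:
    """One summary value per sample over all edge scores (median or maximum).

    The median of an even number of edges is the midpoint of the two central
    values.
    """
    edge_vals = scores.edge_values()
    if edge_vals.shape[1] == 0:
        raise ValueError("score matrix has no edge columns")
    if stat == "median":
        vals = np.median(edge_vals, axis=1)
    elif stat == "max":
        vals = edge_vals.max(axis=1)
    else:
        raise ValueError(f"unknown statistic {stat!r}; expected 'median' or 'max'")
    return pd.Series(vals, index=scores.samples, name=stat)


def decile_rank_index(n_samples: int, fraction: float = 0.2) -> int:
    """k = ⌊n_samples · fraction⌋, the rank of the aggregating order statistic.

    At fraction 0.2 and a 1081-patient cohort this is ⌊1081/5⌋ = 216: the
    216th-highest per-patient score of an edge.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    k = int(np.floor(n_samples * fraction))
    if k < 1:
        raise ValueError(
            f"⌊{n_samples} · {fraction}⌋ = 0: too few samples for this fraction"
        )
    return k


def aggregate_decile(scores: ScoreMatrix, fraction: float = 0.2) -> EdgeRanking:
    """Rank edges by their k-th highest score across samples (k = ⌊n·fraction⌋).

    No interpolation: the aggregate is a raw order statistic, so tied scores
    share the same aggregate value.  The ranking is sorted by descending
    aggregate, ties broken by ascending canonical edge key.
    """
    n = len(scores.samples)
    k = decile_rank_index(n, fraction)
    edge_vals = scores.edge_values()
    if edge_vals.shape[1] == 0:
        raise ValueError("score matrix has no edge columns")
    # k-th highest per column via partial sort
    kth = np.partition(edge_vals, n - k, axis=0)[n - k]
    keys = scores.edge_keys
    order = sorted(range(len(keys)), key=lambda i: (-kth[i], keys[i]))
    entries = tuple((keys[i], float(kth[i])) for i in order)
    return EdgeRanking(entries=entries, fraction=fraction, k=k)


def top_k_edges(ranking: EdgeRanking, k: int) -> set[tuple[str, str]]:
    """The first k edges of the deterministic ranking, as a set of canonical keys."""
    if k < 0 or k > len(ranking):
        raise ValueError(f"k={k} out of range for a ranking of {len(ranking)} edges")
    return {e for e, _ in ranking.entries[:k]}


def write_ranking(ranking: EdgeRanking, path: str | Path) -> None:
    ranking.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
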