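"""Evaluation batteries for the edge scoring.

Two complementary checks of whether high-scoring edges are biologically
meaningful:

1. Survival screening — a univariate Cox proportional-hazards model per edge
   (edge score as the lone covariate), summarized by the generalized
   (Cox–Snell) R² = 1 − exp(−LRT/n), with top-ranked edges compared against
   repeated random edge sets via one-sided Mann–Whitney U tests.
2. Ligand-binding-site (LBS) ranking — per patient, edges incident to an
   LBS-mutated gene are labeled 1 and the patient's score-based edge ranking
   is evaluated by ROC AUC, nDCG and the Spearman correlation p-value,
   against a count-preserving shuffled-LBS null.

A small helper computes the docking disruption ratio (min over the two
receptor/ligand orientations of mutant/wild-type maximum cluster size) used
to compare edge scores with in-silico binding predictions.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .network import ClinicalTable, LBSCatalog, PPINetwork
from .propagate import ScoreMatrix

logger = logging.getLogger("edgesmooth")

LBS_METRICS = ("roc_auc", "ndcg", "spearman_p")


# ---------------------------------------------------------------------------
# survival screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurvivalFitResult:
    """Outcome of one univariate Cox fit.

    ``r2`` is the generalized (Cox–Snell) R² = 1 − exp(−LRT/n) and is only
    meaningful when ``status`` is "ok" or "constant" (a constant covariate
    carries no information, reported as R² = 0 with its own flag); ``beta``
    is the fitted log-hazard coefficient on the original covariate scale.
    """

    edge: tuple[str, str] | None
    r2: float | None
    status: Literal["ok", "constant", "failed"]
    beta: float | None = None

    @property
    def success(self) -> bool:
        return self.status in ("ok", "constant")


def fit_univariate_cox(
    edge_scores: pd.Series | np.ndarray,
    clinical: ClinicalTable,
    edge: tuple[str, str] | None = None,
) -> SurvivalFitResult:
    """Fit survival ~ edge score with a Cox proportional-hazards model.

    ``edge_scores`` is either a Series indexed by sample ID (aligned against
    the clinical table) or an array already in clinical-table order.  Requires
    at least two samples and one observed event.
    """
    if isinstance(edge_scores, pd.Series):
        x = edge_scores.reindex(clinical.samples).to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError("edge scores missing for some clinical samples")
    else:
        x = np.asarray(edge_scores, dtype=float)
        if x.shape[0] != len(clinical.samples):
            raise ValueError("edge scores not aligned with clinical table")
    times = clinical.data["time_days"].to_numpy(dtype=float)
    events = clinical.data["event"].to_numpy(dtype=int)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two samples")
    if events.sum() == 0:
        raise ValueError("all samples censored: no observed events")
    if np.ptp(x) == 0.0:
        return SurvivalFitResult(edge=edge, r2=0.0, status="constant")

    from lifelines import CoxPHFitter

    # standardize the covariate: the partial-likelihood ratio (hence R²) is
    # invariant to affine rescaling, and unit scale keeps Newton steps stable
    z = (x - x.mean()) / x.std()
    df = pd.DataFrame({"time": times, "event": events, "x": z})
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # lifelines raises mixed exception types
        logger.warning("Cox fit failed for edge %s: %s", edge, exc)
        return SurvivalFitResult(edge=edge, r2=None, status="failed")
    lrt = max(float(fitter.log_likelihood_ratio_test().test_statistic), 0.0)
    r2 = 1.0 - math.exp(-lrt / n)
    beta = float(fitter.params_["x"]) / x.std()  # back to the raw covariate scale
    return SurvivalFitResult(edge=edge, r2=r2, status="ok", beta=beta)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #{x_i > y_j} + ½ #{x_i = y_j}."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Literal["greater", "less", "two_sided"] = "greater",
) -> float:
    """Mann–Whitney U test p-value that sample ``x`` is stochastically greater.

    Exact enumeration of all C(n+m, n) group assignments (tie-aware) when both
    samples have at most 8 observations; otherwise the normal approximation
    with tie correction and continuity correction.  "two_sided" measures the
    symmetric deviation of U from its null mean nm/2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = x.size, y.size
    u_obs = _u_statistic(x, y)
    if n <= 8 and m <= 8:
        pooled = np.concatenate([x, y])
        total = math.comb(n + m, n)
        n_ge = n_le = n_dev = 0
        center = n * m / 2.0
        dev_obs = abs(u_obs - center)
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if u >= u_obs - 1e-12:
                n_ge += 1
            if u <= u_obs + 1e-12:
                n_le += 1
            if abs(u - center) >= dev_obs - 1e-12:
                n_dev += 1
        if alternative == "greater":
            return n_ge / total
        if alternative == "less":
            return n_le / total
        return n_dev / total
    # large-sample branch: scipy's tie-corrected normal approximation
    scipy_alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[alternative]
    res = st.mannwhitneyu(x, y, alternative=scipy_alt, method="asymptotic")
    return float(res.pvalue)


def compare_top_vs_random(
    fits: Iterable[SurvivalFitResult],
    top: set[tuple[str, str]],
    n_sets: int = 1000,
    set_size: int = 1000,
    seed: int = 0,
) -> list[float]:
    """One-sided M–W p-values: top edges' R² vs fresh random non-top edge sets.

    Each repetition draws ``set_size`` edges without replacement from the
    successfully fit non-top edges and tests whether the top set's R² values
    are greater.  Reproducible for a given seed.
    """
    top_r2: list[float] = []
    other_r2: list[float] = []
    for fit in fits:
        if not fit.success or fit.r2 is None:
            continue
        if fit.edge in top:
            top_r2.append(fit.r2)
        else:
            other_r2.append(fit.r2)
    if not top_r2:
        raise ValueError("no successful fits among the top edges")
    if set_size > len(other_r2):
        raise ValueError(
            f"cannot draw {set_size} edges from {len(other_r2)} non-top fits"
        )
    other = np.array(other_r2)
    top_arr = np.array(top_r2)
    rng = np.random.default_rng(seed)
    pvals = []
    for _ in range(n_sets):
        sample = rng.choice(other, size=set_size, replace=False)
        pvals.append(mann_whitney_u(top_arr, sample, "greater"))
    return pvals


# ---------------------------------------------------------------------------
# ligand-binding-site ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankingMetrics:
    """Quality of one patient's edge ranking against binary LBS labels."""

    roc_auc: float
    ndcg: float
    spearman_p: float

    def as_dict(self) -> dict[str, float]:
        return {"roc_auc": self.roc_auc, "ndcg": self.ndcg, "spearman_p": self.spearman_p}


def patient_lbs_genes(sample_mutations: set[str], catalog: LBSCatalog) -> set[str]:
    """Genes mutated in this sample that carry an LBS annotation."""
    return sample_mutations & catalog.genes


def label_lbs_edges(
    net: PPINetwork,
    sample_mutations: set[str],
    catalog: LBSCatalog,
) -> np.ndarray:
    """Binary labels over ``net.edge_keys()``: 1 iff an endpoint gene has an
    LBS-annotated mutation in this sample (labels stay binary even when both
    endpoints qualify).  All-zero labelings are allowed and logged."""
    lbs = patient_lbs_genes(sample_mutations, catalog)
    member = np.zeros(net.n_nodes, dtype=bool)
    for g in lbs:
        if net.has_node(g):
            member[net._index[g]] = True
    labels = (member[net.edge_indices[:, 0]] | member[net.edge_indices[:, 1]]).astype(np.int8)
    if not labels.any():
        logger.info("label_lbs_edges: no LBS-incident edges for this sample")
    return labels


def _dcg_binary(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-aware binary DCG: within a tied score block, each positive gets the
    block's average discount, making the value order-independent."""
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    l = labels[order]
    discounts = 1.0 / np.log2(np.arange(2, s.size + 2))
    dcg = 0.0
    i = 0
    while i < s.size:
        j = i
        while j < s.size and s[j] == s[i]:
            j += 1
        n_pos = int(l[i:j].sum())
        if n_pos:
            dcg += n_pos * discounts[i:j].mean()
        i = j
    return dcg


def rank_metrics(scores: Sequence[float], labels: Sequence[int]) -> RankingMetrics:
    """ROC AUC, nDCG and Spearman p for a score-based ranking of binary labels.

    AUC uses the rank-sum statistic with mid-ranks for ties; nDCG discounts
    each positive by 1/log2(rank + 1) and normalizes by the ideal (all
    positives first); the Spearman p-value is the two-sided t-approximation.
    Requires both label classes to be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label classes must be present")
    ranks = st.rankdata(scores)  # ascending, mid-rank ties
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    idcg = float((1.0 / np.log2(np.arange(2, n_pos + 2))).sum())
    ndcg = _dcg_binary(scores, labels) / idcg
    rho_p = st.spearmanr(scores, labels).pvalue
    spearman_p = float(min(max(rho_p, np.nextafter(0, 1)), 1.0))
    return RankingMetrics(roc_auc=float(auc), ndcg=float(ndcg), spearman_p=spearman_p)


def cohort_lbs_metrics(
    net: PPINetwork,
    mutations_by_patient: Mapping[str, set[str]],
    catalog: LBSCatalog,
    scores: ScoreMatrix,
) -> pd.DataFrame:
    """Per-patient ranking metrics for the real LBS labeling.

    Patients whose labeling has a single class (typically no LBS-incident
    edges) are omitted; the returned frame is indexed by the retained samples.
    """
    edge_vals = scores.edge_values()
    rows: dict[str, dict[str, float]] = {}
    for i, sample in enumerate(scores.samples):
        muts = mutations_by_patient.get(sample, set())
        labels = label_lbs_edges(net, muts, catalog)
        if labels.sum() in (0, labels.size):
            continue
        rows[sample] = rank_metrics(edge_vals[i], labels).as_dict()
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample")


def draw_shuffled_labels(
    net: PPINetwork, k: int, pool: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One shuffled labeling: k pseudo-LBS genes drawn without replacement from
    ``pool`` (node indices); returns binary incidence labels over the edges."""
    drawn = rng.choice(pool, size=k, replace=False)
    member = np.zeros(net.n_nodes, dtype=bool)
    member[drawn] = True
    return (member[net.edge_indices[:, 0]] | member[net.edge_indices[:, 1]]).astype(np.int8)


@dataclass
class NullDistribution:
    """Per-permutation metric values under the shuffled-LBS null.

    ``values`` has shape (n_perm, n_patients); entries are NaN when a
    permutation produced a single-class labeling for that patient.
    """

    metric: str
    values: np.ndarray
    seed: int

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_perm(self) -> int:
        return self.values.shape[0]

    @property
    def flat(self) -> np.ndarray:
        """All finite null values pooled across permutations and patients."""
        v = self.values.ravel()
        return v[np.isfinite(v)]


def shuffle_lbs_null(
    net: PPINetwork,
    mutations_by_patient: Mapping[str, set[str]],
    catalog: LBSCatalog,
    scores: ScoreMatrix,
    n_perm: int = 100,
    seed: int = 0,
    universe: Literal["network", "mutated"] = "network",
) -> dict[str, NullDistribution]:
    """Shuffled-LBS null for the three ranking metrics.

    Every permutation redraws, per patient, as many pseudo-LBS genes as the
    patient really has (count-preserving) — uniformly from all network genes
    by default, or from the patient's own network-mutated genes with
    ``universe="mutated"`` — and recomputes the metrics.  On a scale-free
    network the number of edges labeled 1 varies strongly across draws, since
    it depends on the degree of the drawn genes.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    rng = np.random.default_rng(seed)
    edge_vals = scores.edge_values()
    patients: list[tuple[int, int, np.ndarray]] = []  # (row, lbs count, universe idx)
    all_nodes = np.arange(net.n_nodes)
    for i, sample in enumerate(scores.samples):
        muts = mutations_by_patient.get(sample, set())
        k = len(patient_lbs_genes(muts, catalog))
        if k == 0:
            continue
        if universe == "network":
            pool = all_nodes
        else:
            pool = np.array(
                sorted(net._index[g] for g in muts if net.has_node(g)), dtype=int
            )
            if pool.size < k:
                continue
        patients.append((i, k, pool))
    if not patients:
        raise ValueError("no patients with LBS mutations")
    out = {m: np.full((n_perm, len(patients)), np.nan) for m in LBS_METRICS}
    for p in range(n_perm):
        for col, (row, k, pool) in enumerate(patients):
            labels = draw_shuffled_labels(net, k, pool, rng)
            n_pos = int(labels.sum())
            if n_pos in (0, labels.size):
                continue
            metrics = rank_metrics(edge_vals[row], labels)
            for m, v in metrics.as_dict().items():
                out[m][p, col] = v
    return {m: NullDistribution(metric=m, values=v, seed=seed) for m, v in out.items()}


def real_vs_null_pvalues(
    real: pd.DataFrame,
    null: Mapping[str, NullDistribution],
    alternative: Literal["greater", "less", "two_sided"] = "two_sided",
) -> dict[str, float]:
    """M–W p-value per metric comparing real per-patient values to the pooled null."""
    out = {}
    for metric in LBS_METRICS:
        if metric not in real.columns:
            continue
        out[metric] = mann_whitney_u(
            real[metric].to_numpy(), null[metric].flat, alternative
        )
    return out


# ---------------------------------------------------------------------------
# docking disruption
# ---------------------------------------------------------------------------


def docking_disruption_ratio(cluster_sizes: pd.DataFrame) -> float:
    """Minimum over receptor/ligand orientations of mut/WT max-cluster-size ratio.

    ``cluster_sizes`` needs columns ``receptor`` (two distinct orientations),
    ``condition`` ("wt" or "mut") and ``max_cluster_size``; one row per
    orientation × condition.  Lower values mean larger predicted binding
    disruption.
    """
    required = {"receptor", "condition", "max_cluster_size"}
    if not required.issubset(cluster_sizes.columns):
        raise ValueError(f"cluster-size table needs columns {sorted(required)}")
    ratios = []
    for receptor, grp in cluster_sizes.groupby("receptor"):
        sizes = grp.set_index(grp["condition"].str.lower())["max_cluster_size"]
        if "wt" not in sizes.index or "mut" not in sizes.index:
            raise ValueError(f"orientation {receptor!r}: missing wt or mut run")
        wt = float(sizes.loc["wt"])
        if wt <= 0:
            raise ValueError(f"orientation {receptor!r}: non-positive WT cluster size")
        ratios.append(float(sizes.loc["mut"]) / wt)
    if len(ratios) != 2:
        raise ValueError(f"expected 2 receptor/ligand orientations, got {len(ratios)}")
    return min(ratios)


def read_cluster_sizes(path) -> pd.DataFrame:
    """Read the 4-row (receptor, condition, max_cluster_size) TSV for one pair."""
    df = pd.read_csv(path, sep="\t")
    df["max_cluster_size"] = df["max_cluster_size"].astype(float)
    return df
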