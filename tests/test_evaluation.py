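"""Survival screening, ranking metrics, permutation nulls, docking ratios."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

import edgesmooth as es
from edgesmooth.evaluation import draw_shuffled_labels, patient_lbs_genes


def make_clinical(times, events):
    return es.ClinicalTable(
        pd.DataFrame(
            {"time_days": np.asarray(times, dtype=float), "event": np.asarray(events, dtype=int)},
            index=pd.Index([f"S{i}" for i in range(len(times))], name="sample"),
        )
    )


def cox_partial_loglik(beta: float, x: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow partial log-likelihood (tie-free data → identical to Efron)."""
    ll = 0.0
    for i in np.flatnonzero(events):
        risk = times >= times[i]
        ll += beta * x[i] - math.log(np.exp(beta * x[risk]).sum())
    return ll


def cox_oracle_r2(x, times, events):
    """Direct numeric maximization of the partial likelihood."""
    res = scipy.optimize.minimize_scalar(
        lambda b: -cox_partial_loglik(b, x, times, events), bounds=(-50, 50), method="bounded",
        options={"xatol": 1e-10},
    )
    lrt = 2.0 * (-res.fun - cox_partial_loglik(0.0, x, times, events))
    return res.x, 1.0 - math.exp(-max(lrt, 0.0) / len(x))


def simulate_exponential_survival(beta, n, seed, censor_frac=0.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    times = rng.exponential(1.0 / (0.01 * np.exp(beta * x)))
    events = np.ones(n, dtype=int)
    if censor_frac:
        cens = rng.random(n) < censor_frac
        times = np.where(cens, times * rng.random(n), times)
        events = (~cens).astype(int)
    return x, times, events


class TestUnivariateCox:
    def test_recovers_effect_and_matches_oracle(self):
        """β̂ near the simulated log-hazard slope; R² equals the direct
        partial-likelihood maximization to 1e-6."""
        x, times, events = simulate_exponential_survival(beta=1.0, n=200, seed=42)
        fit = es.fit_univariate_cox(x, make_clinical(times, events))
        beta_star, r2_star = cox_oracle_r2(x, times, events)
        assert fit.status == "ok"
        assert fit.beta == pytest.approx(1.0, abs=0.3)
        assert fit.beta == pytest.approx(beta_star, abs=1e-4)
        assert fit.r2 == pytest.approx(r2_star, abs=1e-6)

    def test_oracle_agreement_under_censoring(self):
        x, times, events = simulate_exponential_survival(beta=0.7, n=150, seed=3, censor_frac=0.3)
        fit = es.fit_univariate_cox(x, make_clinical(times, events))
        _, r2_star = cox_oracle_r2(x, times, events)
        assert fit.r2 == pytest.approx(r2_star, abs=1e-6)

    def test_fitted_likelihood_at_least_null(self):
        x, times, events = simulate_exponential_survival(beta=0.0, n=80, seed=7)
        fit = es.fit_univariate_cox(x, make_clinical(times, events))
        assert fit.r2 >= 0.0  # LRT ≥ 0 ⇔ ll(β̂) ≥ ll(0)

    def test_constant_covariate_flagged(self):
        clin = make_clinical([5, 8, 13], [1, 0, 1])
        fit = es.fit_univariate_cox(np.full(3, 0.4), clin)
        assert fit.status == "constant"
        assert fit.r2 == 0.0

    def test_all_censored_rejected(self):
        clin = make_clinical([5, 8, 13], [0, 0, 0])
        with pytest.raises(ValueError, match="censored"):
            es.fit_univariate_cox(np.array([1.0, 2.0, 3.0]), clin)

    def test_r2_invariant_to_affine_rescaling(self):
        x, times, events = simulate_exponential_survival(beta=0.5, n=120, seed=11)
        clin = make_clinical(times, events)
        f1 = es.fit_univariate_cox(x, clin)
        f2 = es.fit_univariate_cox(7.0 * x + 3.0, clin)
        assert f1.r2 == pytest.approx(f2.r2, abs=1e-8)
        assert f2.beta == pytest.approx(f1.beta / 7.0, abs=1e-6)

    def test_series_alignment_by_sample_id(self):
        x, times, events = simulate_exponential_survival(beta=1.0, n=50, seed=5)
        clin = make_clinical(times, events)
        s = pd.Series(x, index=clin.samples)
        shuffled = s.sample(frac=1.0, random_state=0)
        f1 = es.fit_univariate_cox(s, clin)
        f2 = es.fit_univariate_cox(shuffled, clin)
        assert f1.r2 == pytest.approx(f2.r2, abs=1e-12)


def enumeration_oracle_p(x, y, alternative):
    """Independent exact M–W p-value via rank-based U over all assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    u_of = lambda ix: sum(
        scipy.stats.rankdata(pooled)[list(ix)]
    ) - n * (n + 1) / 2.0  # rank-sum formulation of U (mid-ranks)
    u_obs = u_of(range(n))
    count = 0
    total = 0
    for ix in itertools.combinations(range(n + m), n):
        total += 1
        u = u_of(ix)
        if alternative == "greater" and u >= u_obs - 1e-12:
            count += 1
        elif alternative == "less" and u <= u_obs + 1e-12:
            count += 1
        elif alternative == "two_sided" and abs(u - n * m / 2) >= abs(u_obs - n * m / 2) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_exact_separated_samples(self):
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        assert es.mann_whitney_u(y, x, "greater") == pytest.approx(1 / 20)
        assert es.mann_whitney_u(x, y, "greater") == pytest.approx(1.0)
        assert es.mann_whitney_u(x, y, "less") == pytest.approx(1 / 20)

    def test_all_tied_two_sided_is_one(self):
        x = [2.0, 2.0, 2.0]
        assert es.mann_whitney_u(x, x, "two_sided") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("alternative", ["greater", "less", "two_sided"])
    def test_matches_enumeration_oracle(self, seed, alternative):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=5).astype(float)  # ties likely
        y = rng.integers(0, 5, size=6).astype(float)
        assert es.mann_whitney_u(x, y, alternative) == pytest.approx(
            enumeration_oracle_p(x, y, alternative)
        )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(size=7), rng.normal(size=8)
        p = es.mann_whitney_u(x, y, "greater")
        ref = scipy.stats.mannwhitneyu(x, y, alternative="greater", method="exact").pvalue
        assert p == pytest.approx(float(ref), abs=1e-12)

    def test_large_sample_branch_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(0.5, size=35)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic").pvalue
        assert es.mann_whitney_u(x, y, "greater") == pytest.approx(float(ref), abs=1e-12)

    def test_single_swap_moves_p_monotonically(self):
        x = np.array([1.0, 2.0, 6.0])
        y = np.array([3.0, 4.0, 5.0])
        p_before = es.mann_whitney_u(x, y, "greater")
        x2 = np.array([1.0, 2.0, 5.0])
        y2 = np.array([3.0, 4.0, 6.0])  # x loses its maximum
        assert es.mann_whitney_u(x2, y2, "greater") > p_before

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            es.mann_whitney_u([], [1.0], "greater")


class TestCompareTopVsRandom:
    def _fits(self, top_r2, other_r2):
        fits = []
        for i, r2 in enumerate(top_r2):
            fits.append(es.SurvivalFitResult(edge=(f"T{i}", f"U{i}"), r2=r2, status="ok"))
        for i, r2 in enumerate(other_r2):
            fits.append(es.SurvivalFitResult(edge=(f"X{i}", f"Y{i}"), r2=r2, status="ok"))
        top = {f.edge for f in fits[: len(top_r2)]}
        return fits, top

    def test_complete_separation_gives_tiny_p(self):
        rng = np.random.default_rng(0)
        fits, top = self._fits(0.9 + 0.01 * rng.random(30), 0.1 * rng.random(200))
        pvals = es.compare_top_vs_random(fits, top, n_sets=20, set_size=30, seed=1)
        assert max(pvals) < 0.001

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        fits, top = self._fits(rng.random(20), rng.random(100))
        a = es.compare_top_vs_random(fits, top, n_sets=10, set_size=20, seed=5)
        b = es.compare_top_vs_random(fits, top, n_sets=10, set_size=20, seed=5)
        assert a == b

    def test_insufficient_pool_rejected(self):
        fits, top = self._fits([0.5] * 5, [0.4] * 3)
        with pytest.raises(ValueError):
            es.compare_top_vs_random(fits, top, n_sets=2, set_size=10, seed=0)

    def test_failed_fits_excluded(self):
        fits, top = self._fits([0.5, 0.6], [0.1, 0.2, 0.3, 0.4])
        fits.append(es.SurvivalFitResult(edge=("Z", "Z2"), r2=None, status="failed"))
        pvals = es.compare_top_vs_random(fits, top, n_sets=3, set_size=4, seed=0)
        assert len(pvals) == 3

    def test_null_pvalue_uniformity(self):
        """With no real effect, one-sided M–W p-values are uniform: the
        rejection rate at 0.05 stays within 0.05 ± 0.02."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            if es.mann_whitney_u(rng.normal(size=30), rng.normal(size=30), "greater") < 0.05:
                hits += 1
        assert abs(hits / n_rep - 0.05) <= 0.02


class TestLBSLabeling:
    def _star(self, k=5):
        return es.PPINetwork.from_edge_list([("HUB", f"L{i}", 0.5) for i in range(k)])

    def test_degree_many_incident_labels(self):
        net = self._star(5)
        catalog = es.LBSCatalog({"HUB": {"F293L"}})
        labels = es.label_lbs_edges(net, {"HUB", "L0"}, catalog)
        assert labels.sum() == 5  # every edge touching the LBS gene

    def test_no_lbs_mutations_all_zero(self):
        net = self._star(4)
        catalog = es.LBSCatalog({"HUB": {"F293L"}})
        labels = es.label_lbs_edges(net, {"L0", "L1"}, catalog)
        assert not labels.any()

    def test_shared_edge_stays_binary(self):
        net = es.PPINetwork.from_edge_list([("A", "B", 0.9)])
        catalog = es.LBSCatalog({"A": {"F293L"}, "B": {"S46C"}})
        labels = es.label_lbs_edges(net, {"A", "B"}, catalog)
        np.testing.assert_array_equal(labels, [1])

    def test_catalog_gene_must_be_mutated(self):
        net = self._star(3)
        catalog = es.LBSCatalog({"HUB": {"F293L"}})
        assert patient_lbs_genes({"L0"}, catalog) == set()
        assert patient_lbs_genes({"HUB"}, catalog) == {"HUB"}


def brute_force_auc(scores, labels):
    """Fraction of correctly ordered (positive, negative) pairs, ½ for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRankMetrics:
    def test_perfect_ranking(self):
        m = es.rank_metrics([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert m.roc_auc == pytest.approx(1.0)
        assert m.ndcg == pytest.approx(1.0)

    def test_reversed_ranking(self):
        m = es.rank_metrics([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert m.roc_auc == pytest.approx(0.0)

    def test_tied_positives_on_top_still_perfect(self):
        m = es.rank_metrics([0.5, 0.5, 0.1], [1, 1, 0])
        assert m.ndcg == pytest.approx(1.0)
        assert m.roc_auc == pytest.approx(1.0)

    def test_imperfect_ranking_has_ndcg_below_one(self):
        m = es.rank_metrics([0.9, 0.5, 0.7], [1, 1, 0])
        assert 0.0 < m.ndcg < 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_matches_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 50))
        scores = rng.choice(np.linspace(0, 1, 11), size=n)  # tie-rich
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0], labels[-1] = 1, 0
        m = es.rank_metrics(scores, labels)
        assert m.roc_auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_ndcg_matches_hand_computation(self):
        # ranking: pos(1), neg(2), pos(3) → DCG = 1 + 1/log2(4); IDCG = 1 + 1/log2(3)
        m = es.rank_metrics([0.9, 0.6, 0.3], [1, 0, 1])
        expected = (1.0 + 1.0 / math.log2(4)) / (1.0 + 1.0 / math.log2(3))
        assert m.ndcg == pytest.approx(expected, abs=1e-12)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(99)
        labels = np.zeros(1000, dtype=int)
        labels[:50] = 1
        aucs = [
            es.rank_metrics(rng.random(1000), labels).roc_auc for _ in range(100)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            es.rank_metrics([0.1, 0.2], [1, 1])

    def test_spearman_p_in_unit_interval(self):
        rng = np.random.default_rng(4)
        m = es.rank_metrics(rng.random(50), rng.integers(0, 2, 50))
        assert 0.0 < m.spearman_p <= 1.0


class TestShuffleNull:
    def test_count_preservation_and_degree_dependence(self):
        """Shuffled draws keep each patient's LBS-gene count; on a hub-and-spoke
        graph the number of positive edges varies with the drawn genes' degree."""
        net = es.PPINetwork.from_edge_list(
            [("HUB", f"L{i}", 0.5) for i in range(8)] + [("L0", "L1", 0.5)]
        )
        rng = np.random.default_rng(0)
        pool = np.arange(net.n_nodes)
        counts = set()
        for _ in range(30):
            labels = draw_shuffled_labels(net, 1, pool, rng)
            counts.add(int(labels.sum()))
        assert len(counts) > 1  # hub draw labels 8 edges, leaf draws 1-3
        assert max(counts) == 8

    def test_identity_permutation_reproduces_real_metrics(self, study):
        """A shuffle that redraws exactly the real LBS genes gives identical labels."""
        net, catalog = study["net"], study["catalog"]
        muts = study["mutations_by_patient"]
        sample = next(s for s in study["scores"].samples
                      if patient_lbs_genes(muts[s], catalog))
        real = es.label_lbs_edges(net, muts[sample], catalog)
        genes = sorted(patient_lbs_genes(muts[sample], catalog))
        idx = np.array([net._index[g] for g in genes])
        class FixedRNG:
            def choice(self, pool, size, replace):
                return idx
        same = draw_shuffled_labels(net, len(idx), idx, FixedRNG())
        np.testing.assert_array_equal(same, real)

    def test_null_reproducible_and_shaped(self, study):
        net, catalog, scores = study["net"], study["catalog"], study["scores"]
        muts = study["mutations_by_patient"]
        a = es.shuffle_lbs_null(net, muts, catalog, scores, n_perm=2, seed=9)
        b = es.shuffle_lbs_null(net, muts, catalog, scores, n_perm=2, seed=9)
        for metric in a:
            assert a[metric].n_perm == 2
            np.testing.assert_array_equal(a[metric].values, b[metric].values)


class TestDockingDisruption:
    def _table(self, wt_a, mut_a, wt_b, mut_b):
        return pd.DataFrame(
            {
                "receptor": ["A", "A", "B", "B"],
                "condition": ["wt", "mut", "wt", "mut"],
                "max_cluster_size": [wt_a, mut_a, wt_b, mut_b],
            }
        )

    def test_no_change_gives_one(self):
        assert es.docking_disruption_ratio(self._table(100, 100, 80, 80)) == pytest.approx(1.0)

    def test_halved_clusters(self):
        assert es.docking_disruption_ratio(self._table(100, 50, 100, 50)) == pytest.approx(0.5)

    def test_minimum_of_orientations(self):
        assert es.docking_disruption_ratio(self._table(100, 80, 100, 60)) == pytest.approx(0.6)

    def test_missing_orientation_rejected(self):
        table = self._table(100, 80, 100, 60).iloc[:3]
        with pytest.raises(ValueError):
            es.docking_disruption_ratio(table)

    def test_zero_wt_rejected(self):
        with pytest.raises(ValueError):
            es.docking_disruption_ratio(self._table(0, 10, 100, 60))
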