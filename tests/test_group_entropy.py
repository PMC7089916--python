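import math

import numpy as np
import pytest

from assocpat.group_entropy import (
    CompositionDistribution,
    composition_distribution,
    entropy_ratio,
    entropy_report,
    expected_entropy,
    js_distance,
    kl_divergence,
    shannon_entropy,
)
from assocpat.null_model import build_ensemble

from conftest import make_dataset, make_roster, random_dataset


def dist(probs_by_label):
    """CompositionDistribution from {label: prob} using singleton frozensets."""
    return CompositionDistribution(
        probs={frozenset({k}): v for k, v in probs_by_label.items()},
        n_scans=10**6,
    )


# independent oracles: plain-python evaluation of the defining formulas
def entropy_oracle(probs):
    return -sum(p * math.log2(p) for p in probs if p > 0)


def kl_oracle(p, q):
    return sum(pi * math.log2(pi / qi) for pi, qi in zip(p, q) if pi > 0)


class TestCompositionDistribution:
    def test_identical_scans_single_composition(self, roster5):
        ds = make_dataset(roster5, [[0, 1]] * 4)
        d = composition_distribution(ds)
        assert d.support_size == 1
        assert list(d.probs.values()) == [1.0]

    def test_distinct_scans_uniform(self, roster5):
        ds = make_dataset(roster5, [[0, 1], [0, 2], [0, 3], [0, 4]])
        d = composition_distribution(ds)
        assert d.support_size == 4
        assert all(v == pytest.approx(0.25) for v in d.probs.values())

    def test_counts_to_probabilities(self, roster5):
        ds = make_dataset(roster5, [[0, 1]] * 3 + [[0, 2]])
        d = composition_distribution(ds)
        assert sorted(d.probs.values()) == [pytest.approx(0.25), pytest.approx(0.75)]


class TestShannonEntropy:
    def test_uniform_four(self):
        assert shannon_entropy(dist({"a": 0.25, "b": 0.25, "c": 0.25, "d": 0.25})) == pytest.approx(2.0)

    def test_single_composition_zero(self):
        assert shannon_entropy(dist({"a": 1.0})) == 0.0

    def test_worked_value(self):
        assert shannon_entropy(dist({"a": 0.75, "b": 0.25})) == pytest.approx(0.8113, abs=1e-4)

    def test_matches_oracle_on_random_distributions(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 12))
            p = rng.dirichlet(np.ones(k))
            labels = {str(i): pi for i, pi in enumerate(p)}
            assert shannon_entropy(dist(labels)) == pytest.approx(entropy_oracle(p), abs=1e-9)

    def test_entropy_bounded_by_log_support(self, rng):
        ds = random_dataset(rng, n=5, n_scans=40)
        d = composition_distribution(ds)
        h = shannon_entropy(d)
        assert h <= math.log2(d.support_size) + 1e-12
        assert h <= math.log2(ds.n_scans) + 1e-12


class TestDivergences:
    def test_kl_zero_for_identical(self):
        d = dist({"a": 0.3, "b": 0.7})
        assert kl_divergence(d, d) == pytest.approx(0.0, abs=1e-12)

    def test_kl_worked_value(self):
        p = dist({"a": 0.5, "b": 0.5})
        q = dist({"a": 0.75, "b": 0.25})
        assert kl_divergence(p, q) == pytest.approx(0.2075, abs=1e-4)

    def test_kl_nonnegative_random_pairs(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 10))
            p, q = rng.dirichlet(np.ones(k)), rng.dirichlet(np.ones(k))
            labels = [str(i) for i in range(k)]
            P = dist(dict(zip(labels, p)))
            Q = dist(dict(zip(labels, q)))
            kl = kl_divergence(P, Q)
            assert kl >= -1e-12
            assert kl == pytest.approx(kl_oracle(p, q), abs=1e-9)

    def test_kl_support_mismatch_needs_epsilon(self):
        p = dist({"a": 0.5, "b": 0.5})
        q = dist({"a": 1.0})
        with pytest.raises(ValueError):
            kl_divergence(p, q, epsilon=0.0)
        assert np.isfinite(kl_divergence(p, q, epsilon=1e-6))

    def test_js_identical_zero_and_disjoint_one(self):
        d = dist({"a": 0.4, "b": 0.6})
        assert js_distance(d, d) == pytest.approx(0.0, abs=1e-12)
        assert js_distance(dist({"a": 1.0}), dist({"b": 1.0})) == pytest.approx(1.0)

    def test_js_symmetric_and_bounded(self, rng):
        for _ in range(25):
            k = int(rng.integers(2, 8))
            labels = [str(i) for i in range(k)]
            P = dist(dict(zip(labels, rng.dirichlet(np.ones(k)))))
            Q = dist(dict(zip(labels, rng.dirichlet(np.ones(k)))))
            assert js_distance(P, Q) == pytest.approx(js_distance(Q, P), abs=1e-12)
            assert 0.0 <= js_distance(P, Q) <= 1.0


class TestEntropyRatio:
    def test_conventions(self):
        assert entropy_ratio(2.0, 2.0) == 1.0
        assert entropy_ratio(0.0, 0.0) == 1.0
        assert entropy_ratio(0.0, 3.0) == 0.0
        with pytest.raises(ValueError):
            entropy_ratio(1.0, 0.0)

    def test_paper_scale_rounding(self):
        # 11.83 observed vs 11.84 expected rounds to a ratio of 1
        assert entropy_ratio(11.83, 11.84) == pytest.approx(1.0, abs=1e-3)


class TestEntropyReportAndEnsemble:
    def test_degenerate_two_member_roster_zero_expected_entropy(self):
        roster = make_roster(2)
        ds = make_dataset(roster, [[0, 1], [1, 0]], focals=[0, 1])
        ens = build_ensemble(ds, B=5, seed=1)
        # size-2 scans on a 2-member roster admit one composition only
        mean, sd = expected_entropy(ens)
        assert mean == 0.0
        rep = entropy_report(ds, ens)
        assert rep.H_obs == 0.0 and rep.ratio == 1.0

    def test_single_realization_warns_sd_zero(self, rng):
        ds = random_dataset(rng, n=5, n_scans=10)
        ens = build_ensemble(ds, B=1, seed=1)
        with pytest.warns(UserWarning, match="B=1"):
            mean, sd = expected_entropy(ens)
        assert sd == 0.0

    def test_report_fields_consistent(self, rng):
        ds = random_dataset(rng, n=6, n_scans=60)
        ens = build_ensemble(ds, B=30, seed=4)
        rep = entropy_report(ds, ens)
        assert rep.unique_obs <= ds.n_scans
        assert 0 < rep.unique_frac <= 1.0
        assert rep.H_obs == pytest.approx(shannon_entropy(composition_distribution(ds)))
        assert rep.ratio == pytest.approx(rep.H_obs / rep.H_exp)
        assert 0.0 <= rep.JS_distance <= 1.0
        assert rep.KL >= 0.0

    def test_all_identical_scans(self, roster5):
        ds = make_dataset(roster5, [[0, 1, 2]] * 8)
        ens = build_ensemble(ds, B=10, seed=2)
        rep = entropy_report(ds, ens)
        assert rep.H_obs == 0.0
        assert rep.unique_frac == pytest.approx(1 / 8)

    def test_bias_experiment_is_seed_deterministic(self):
        from assocpat.group_entropy import bias_experiment

        a = bias_experiment(group_sizes=(8,), scan_counts=(100,), replicates=2, B=10, seed=3)
        b = bias_experiment(group_sizes=(8,), scan_counts=(100,), replicates=2, B=10, seed=3)
        assert a.equals(b)

    def test_pooled_entropy_at_least_mean_realization_entropy(self, rng):
        """Concavity: entropy of the pooled null distribution >= mean per-realization entropy."""
        ds = random_dataset(rng, n=6, n_scans=50)
        ens = build_ensemble(ds, B=40, seed=6)
        pooled_p = ens.pooled_counts / ens.pooled_counts.sum()
        pooled_h = -(pooled_p * np.log2(pooled_p)).sum()
        assert pooled_h >= ens.entropies.mean() - 1e-9
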