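"""Good's u, SQS, zero-truncated Poisson MLE and TRiPS estimates."""

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import bisect

from paleospread.richness import (
    SQSConfig,
    aggregate_replicates,
    estimate_all,
    estimate_pool,
    goods_u,
    sqs_richness,
    sqs_trial_richness,
    trips_richness,
    ztp_lambda_mle,
    ztp_lambda_profile_ci,
)
from paleospread.synthetic import generate_trips_counts

from conftest import make_record


class TestGoodsU:
    def test_all_multi_collection_taxa_full_coverage(self):
        pool = [make_record(i, t, coll=c) for i, (t, c) in
                enumerate([("A", "c1"), ("A", "c2"), ("B", "c1"), ("B", "c2")])]
        assert goods_u(pool) == 1.0

    def test_all_singletons_zero_coverage(self):
        pool = [make_record(i, f"t{i}", coll=f"c{i}") for i in range(10)]
        assert goods_u(pool) == 0.0

    def test_three_singletons_in_ten(self):
        # 3 single-collection taxa among 10 occurrences -> u = 0.7
        occ = [("A", "c1"), ("A", "c2"), ("B", "c1"), ("B", "c2"), ("C", "c1"),
               ("C", "c2"), ("C", "c3"), ("X", "c1"), ("Y", "c2"), ("Z", "c3")]
        pool = [make_record(i, t, coll=c) for i, (t, c) in enumerate(occ)]
        assert goods_u(pool) == pytest.approx(0.7)

    def test_by_occurrence_rule_differs(self):
        # taxon A has 2 occurrences in ONE collection: singleton by
        # collection, not by occurrence
        occ = [("A", "c1"), ("A", "c1"), ("B", "c1"), ("B", "c2")]
        pool = [make_record(i, t, coll=c) for i, (t, c) in enumerate(occ)]
        assert goods_u(pool, "by_collection") == pytest.approx(0.75)
        assert goods_u(pool, "by_occurrence") == 1.0

    def test_empty_pool_not_available(self):
        assert goods_u([]) is None


class TestSQS:
    def test_mean_equals_exhaustive_permutation_expectation(
        self, three_collection_pool
    ):
        cfg = SQSConfig(quorum=0.4, n_trials=4000)
        u = goods_u(three_collection_pool)
        exact = np.mean(
            [
                sqs_trial_richness(three_collection_pool, perm, cfg, u)
                for perm in itertools.permutations(["c1", "c2", "c3"])
            ]
        )
        mean, _ = sqs_richness(three_collection_pool, cfg, rng=7)
        assert mean == pytest.approx(exact, abs=0.05)

    def test_full_coverage_pool_at_quorum_one_draws_everything(self):
        occ = [("A", "c1"), ("A", "c2"), ("B", "c1"), ("B", "c2"),
               ("C", "c1"), ("C", "c2")]
        pool = [make_record(i, t, coll=c) for i, (t, c) in enumerate(occ)]
        assert goods_u(pool) == 1.0
        mean, sd = sqs_richness(pool, SQSConfig(quorum=1.0, n_trials=50), rng=0)
        assert mean == 3.0 and sd == 0.0

    def test_tiny_quorum_draws_about_one_collection(self, three_collection_pool):
        mean, _ = sqs_richness(
            three_collection_pool, SQSConfig(quorum=1e-9, n_trials=500), rng=0
        )
        # first drawn collection always satisfies the quorum
        assert 1.0 <= mean <= 4.0

    def test_quorum_above_u_not_available(self, three_collection_pool):
        u = goods_u(three_collection_pool)
        assert sqs_richness(three_collection_pool, SQSConfig(quorum=u + 0.01)) is None

    def test_mean_nondecreasing_in_quorum(self, three_collection_pool):
        means = []
        for q in (0.2, 0.4, 0.6):
            m, _ = sqs_richness(
                three_collection_pool, SQSConfig(quorum=q, n_trials=600), rng=11
            )
            means.append(m)
        assert means == sorted(means)

    def test_scale_invariance_under_duplication(self, rng):
        # doubling every collection (same shape) moves the estimate < 5%
        taxa = [f"t{i}" for i in range(12)]
        occ = []
        for c in range(8):
            for t in rng.choice(taxa, size=6):
                occ.append((str(t), f"c{c}"))
        pool = [make_record(i, t, coll=c) for i, (t, c) in enumerate(occ)]
        doubled = pool + [
            make_record(1000 + i, r.taxon_name, coll=r.collection_id + "_dup")
            for i, r in enumerate(pool)
        ]
        cfg = SQSConfig(quorum=0.4, n_trials=600)
        m1, _ = sqs_richness(pool, cfg, rng=3)
        m2, _ = sqs_richness(doubled, cfg, rng=3)
        assert abs(m2 - m1) / m1 < 0.05

    def test_excluding_dominant_taxon_needs_more_draws(self, three_collection_pool):
        # without the dominant taxon's share, coverage accrues slower, so
        # trials draw at least as many collections -> richness never lower
        base = SQSConfig(quorum=0.4, n_trials=800)
        excl = SQSConfig(quorum=0.4, n_trials=800, exclude_dominant=True)
        m_base, _ = sqs_richness(three_collection_pool, base, rng=5)
        m_excl, _ = sqs_richness(three_collection_pool, excl, rng=5)
        assert m_excl >= m_base

    def test_deterministic_given_seed(self, three_collection_pool):
        cfg = SQSConfig(n_trials=50)
        assert sqs_richness(three_collection_pool, cfg, rng=42) == sqs_richness(
            three_collection_pool, cfg, rng=42
        )


class TestZTP:
    def test_all_singleton_counts_hit_zero_boundary(self):
        assert ztp_lambda_mle([1, 1, 1, 1]) == 0.0

    def test_mean_two_root(self):
        # independent bisection oracle for lambda/(1-e^-lambda) = 2
        oracle = bisect(lambda l: l / (1 - math.exp(-l)) - 2.0, 1e-9, 10, xtol=1e-12)
        assert ztp_lambda_mle([1, 3, 2, 2]) == pytest.approx(oracle, abs=1e-10)

    def test_residual_below_tolerance(self):
        counts = [1, 2, 2, 3, 1, 4, 2]
        lam = ztp_lambda_mle(counts)
        assert abs(lam / (1 - math.exp(-lam)) - np.mean(counts)) < 1e-10

    def test_simulation_consistency(self):
        counts = generate_trips_counts(10_000, 1.0, rng=77)
        assert ztp_lambda_mle(counts) == pytest.approx(1.0, abs=0.05)

    def test_profile_ci_brackets_mle(self):
        counts = generate_trips_counts(200, 1.2, rng=5)
        lam, lo, hi = ztp_lambda_profile_ci(counts)
        assert lo < lam < hi

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            ztp_lambda_mle([0, 1, 2])


class TestTrips:
    def test_saturation_richness_tends_to_observed(self):
        est = trips_richness([40, 45, 50, 38, 42])
        assert est.p_hat > 0.999999
        assert est.richness_hat == pytest.approx(5, rel=1e-5)

    def test_mean_two_over_fifty_taxa(self):
        counts = [1, 3] * 25  # mean exactly 2 over 50 taxa
        est = trips_richness(counts)
        assert est.p_hat == pytest.approx(1 - math.exp(-1.59362), abs=1e-4)
        assert est.richness_hat == pytest.approx(62.8, abs=0.2)

    def test_degenerate_all_singletons_flagged(self):
        est = trips_richness([1, 1, 1])
        assert est.degenerate and est.richness_hat == math.inf

    def test_richness_at_least_observed_and_p_monotone(self):
        prev_p = 0.0
        for second_count in (2, 3, 5, 7):
            counts = [1, second_count] * 20
            est = trips_richness(counts)
            assert est.richness_hat >= est.n_observed
            assert est.p_hat > prev_p  # p strictly increasing in lambda
            prev_p = est.p_hat

    def test_ci_orders_around_estimate(self):
        est = trips_richness(generate_trips_counts(200, 1.5, rng=8))
        assert est.ci_low <= est.richness_hat <= est.ci_high


class TestEstimateAggregation:
    def test_identical_replicates_aggregate_to_same_value(self, three_collection_pool):
        ests = [
            estimate_pool(three_collection_pool, "R", "B1", i, SQSConfig(n_trials=100), rng=9)
            for i in range(3)
        ]
        agg = aggregate_replicates(ests)
        assert agg.raw == ests[0].raw
        assert agg.sqs_mean == pytest.approx(ests[0].sqs_mean)
        assert agg.sqs_sd == pytest.approx(0.0)

    def test_mean_of_two_values(self, three_collection_pool):
        a = estimate_pool(three_collection_pool, "R", "B1", 0, rng=1)
        b = estimate_pool(three_collection_pool, "R", "B1", 1, rng=1)
        a.sqs_mean, b.sqs_mean = 10.0, 20.0
        agg = aggregate_replicates([a, b])
        assert agg.sqs_mean == 15.0

    def test_empty_replicate_list_not_available(self):
        assert aggregate_replicates([]) is None

    def test_estimate_all_mixes_modes_and_aggregates(self, three_collection_pool):
        pools = {
            ("R1", "B1"): three_collection_pool,  # unstandardized
            ("R1", "B2"): [three_collection_pool, three_collection_pool],
        }
        out = estimate_all(pools, SQSConfig(n_trials=50), master_seed=3)
        kinds = [(e.bin, e.replicate_id) for e in out]
        assert ("B1", "regional") in kinds
        assert ("B2", "aggregated") in kinds
        assert ("B2", 0) in kinds and ("B2", 1) in kinds
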