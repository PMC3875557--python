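"""Net enrichment, threshold target calling and hypergeometric overlap."""

import itertools
import math
import statistics
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from whi3kit.io_formats import RipExperiment
from whi3kit.ripchip_targets import call_targets, net_enrichment, overlap_test
from whi3kit.synthetic_data import SimulationConfig, generate_ripchip


class TestNetEnrichment:
    def test_two_experiment_average(self):
        exps = [
            RipExperiment("e1", {"g": 2.0}, {"g": 0.5}),
            RipExperiment("e2", {"g": 1.0}, {"g": 0.5}),
        ]
        assert net_enrichment(exps) == {"g": pytest.approx(1.0)}

    def test_ip_equal_control_gives_zero(self):
        exps = [RipExperiment("e1", {"a": 1.2, "b": -0.5}, {"a": 1.2, "b": -0.5})]
        assert net_enrichment(exps) == {"a": 0.0, "b": 0.0}

    def test_empty_experiment_set_errors(self):
        with pytest.raises(ValueError):
            net_enrichment([])

    def test_genes_missing_from_one_experiment_are_dropped(self):
        exps = [
            RipExperiment("e1", {"a": 1.0, "b": 2.0}, {"a": 0.0, "b": 0.0}),
            RipExperiment("e2", {"a": 3.0}, {"a": 0.0}),
        ]
        assert set(net_enrichment(exps)) == {"a"}

    @given(
        st.dictionaries(
            st.text(alphabet="abcdefgh", min_size=1, max_size=3),
            st.tuples(
                st.floats(-10, 10, allow_nan=False),
                st.floats(-10, 10, allow_nan=False),
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_swapping_ip_and_control_negates_the_net(self, ratios):
        ip = {g: v[0] for g, v in ratios.items()}
        ctrl = {g: v[1] for g, v in ratios.items()}
        fwd = net_enrichment([RipExperiment("e", ip, ctrl)])
        rev = net_enrichment([RipExperiment("e", ctrl, ip)])
        for g in ratios:
            assert fwd[g] == pytest.approx(-rev[g], abs=1e-12)


class TestCallTargets:
    def test_forced_arithmetic_example(self):
        net = {"a": 3.0, "b": 0.0, "c": 0.0, "d": 0.0, "e": 0.0}
        call = call_targets(net)
        expected = 0.6 + 1.65 * statistics.stdev([3.0, 0, 0, 0, 0])
        assert call.threshold == pytest.approx(expected)
        assert call.threshold == pytest.approx(2.8137, abs=1e-4)
        assert call.targets == ["a"]

    def test_zero_variance_yields_no_targets(self):
        call = call_targets({"a": 1.0, "b": 1.0, "c": 1.0})
        assert call.targets == []

    def test_fewer_than_two_genes_errors(self):
        with pytest.raises(ValueError):
            call_targets({"a": 1.0})

    def test_matches_brute_force_recomputation_on_synthetic_data(self, cfg, genes):
        experiments, _ = generate_ripchip(cfg, genes)
        net = net_enrichment(experiments)
        call = call_targets(net)
        # independent recomputation with the statistics module
        vals = list(net.values())
        thr = statistics.fmean(vals) + 1.65 * statistics.stdev(vals)
        brute = sorted((g for g, v in net.items() if v > thr), key=lambda g: (-net[g], g))
        assert call.threshold == pytest.approx(thr)
        assert call.targets == brute

    def test_sensitivity_and_fdr_on_planted_effect(self, genes):
        cfg = SimulationConfig(seed=7, enrichment_effect=3.0, rip_noise_sd=0.5)
        experiments, truth = generate_ripchip(cfg, genes)
        call = call_targets(net_enrichment(experiments))
        truth_set, called = set(truth), set(call.targets)
        assert len(called & truth_set) / len(truth_set) >= 0.95
        assert len(called - truth_set) / max(len(called), 1) <= 0.10

    def test_ranking_is_descending_with_lexicographic_ties(self):
        net = {"b": 5.0, "a": 5.0, "c": 4.0, "d": 0.0, "e": 0.0, "f": 0.0}
        call = call_targets(net, z_cutoff=0.5)
        assert call.targets == sorted(call.targets, key=lambda g: (-net[g], g))


def brute_force_overlap_tail(N, K, n, k):
    """Exact P(overlap >= k) by enumeration of all draws (tiny N only)."""
    universe = range(N)
    listA = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(listA & set(draw)) >= k:
            hits += 1
    return hits / total


class TestOverlapTest:
    def test_identical_two_element_lists_in_universe_of_four(self):
        r = overlap_test({"1", "2"}, {"1", "2"}, 4)
        assert r.overlap == 2
        assert r.p_value == pytest.approx(1 / 6)

    def test_disjoint_lists_have_p_one(self):
        r = overlap_test({"a"}, {"b"}, 10)
        assert r.overlap == 0 and r.p_value == 1.0

    def test_universe_smaller_than_union_errors(self):
        with pytest.raises(ValueError):
            overlap_test({"a", "b"}, {"c", "d"}, 3)

    @pytest.mark.parametrize("N,K,n", [(5, 2, 3), (8, 4, 4), (10, 6, 5), (12, 5, 7)])
    def test_agrees_with_exhaustive_enumeration(self, N, K, n):
        A = set(range(K))
        for k_target in range(max(0, K + n - N), min(K, n) + 1):
            # realize an overlap of exactly k_target
            B = set(range(k_target)) | set(range(K, K + n - k_target))
            r = overlap_test(A, B, N)
            assert r.overlap == k_target
            assert r.p_value == pytest.approx(
                brute_force_overlap_tail(N, K, n, k_target), rel=1e-9
            )

    def test_extreme_overlap_magnitude_against_exact_oracle(self):
        # two published target lists: 111 shared of 326 and 262 in ~6000 genes
        N, K, n, k = 6000, 326, 262, 111
        A = set(range(K))
        B = set(range(k)) | set(range(K, K + n - k))
        r = overlap_test(A, B, N)
        exact = sum(
            Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
            for i in range(k, min(K, n) + 1)
        )
        assert r.log10_p == pytest.approx(math.log10(float(exact)), abs=1e-6)
        # order of magnitude of the published overlap p-value (~1e-74)
        assert -80 < r.log10_p < -70
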