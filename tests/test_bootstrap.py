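from math import comb

import numpy as np
import pytest

import crowdecg as cc
from crowdecg.bootstrap import (
    BootstrapConfig,
    cycle_average_accuracy,
    estimate,
    sample_group,
    sweep,
)
from crowdecg.errors import ConfigError
from crowdecg.metrics import MetricSpec

from conftest import make_dataset


def _degenerate_dataset(gold=True, n=8):
    """Every reader gives the same answer: the gold one, or a wrong one."""
    label = "G" if gold else "W"
    return make_dataset(
        [("c", ["G"], "easy")],
        [(f"r{i}", "c", [label], 4, "recent_graduate") for i in range(n)],
    ).validate()


class TestSampleGroup:
    def test_full_population_when_n_equals_size(self, rng):
        readers = [f"r{i}" for i in range(5)]
        assert sorted(sample_group(readers, 5, rng)) == readers

    def test_oversized_group_rejected(self, rng):
        with pytest.raises(ValueError, match="group of 31 from 30"):
            sample_group([f"r{i}" for i in range(30)], 31, rng)

    def test_subsets_uniform(self):
        """All C(6,3)=20 subsets appear with frequency 0.05 +/- 4 sigma over
        100,000 draws (exact multinomial oracle)."""
        readers = list("abcdef")
        rng = np.random.default_rng(17)
        n_draws = 100_000
        counts: dict[tuple, int] = {}
        for _ in range(n_draws):
            key = tuple(sorted(sample_group(readers, 3, rng)))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == comb(6, 3)
        p = 1 / comb(6, 3)
        sigma = (p * (1 - p) / n_draws) ** 0.5
        for key, c in counts.items():
            assert abs(c / n_draws - p) < 4 * sigma, key


class TestCycleAverage:
    def test_all_gold_population_scores_one_everywhere(self, rng):
        ds = _degenerate_dataset(gold=True)
        for protocol in cc.PROTOCOLS:
            for ms in (MetricSpec("SA"), MetricSpec("LA", 5)):
                v = cycle_average_accuracy(ds, "c", protocol, ms, 3, 50, rng)
                assert v == 1.0

    def test_never_gold_population_scores_zero_sa(self, rng):
        ds = _degenerate_dataset(gold=False)
        assert cycle_average_accuracy(ds, "c", "frequency", MetricSpec("SA"), 3, 50, rng) == 0.0

    def test_converges_to_enumeration(self, six_reader_case):
        """Monte Carlo cycle average approaches the exact all-groups value
        (20 groups of size 3), within 2 standard errors."""
        exact = cc.exact_average_accuracy(
            six_reader_case, "c1", "frequency", MetricSpec("SA"), 3
        )
        n = 20_000
        v = cycle_average_accuracy(
            six_reader_case, "c1", "frequency", MetricSpec("SA"), 3, n,
            np.random.default_rng(5),
        )
        se = (exact * (1 - exact) / n) ** 0.5
        assert abs(v - exact) < 2 * se

    def test_oversized_group_rejected(self, six_reader_case, rng):
        with pytest.raises(ValueError, match="exceeds"):
            cycle_average_accuracy(
                six_reader_case, "c1", "frequency", MetricSpec("SA"), 7, 10, rng
            )


class TestEstimate:
    CFG = BootstrapConfig(n_cycles=50, n_samples=50, n_boots=100, group_sizes=(3,), seed=11)

    def test_degenerate_population_collapses_ci(self):
        ds = _degenerate_dataset(gold=True)
        est = estimate(ds, "c", "frequency", MetricSpec("SA"), 3, self.CFG)
        assert (est.mean, est.sd, est.ci_low, est.ci_high) == (1.0, 0.0, 1.0, 1.0)

    def test_fixed_seed_is_bit_reproducible(self, six_reader_case):
        a = estimate(six_reader_case, "c1", "confidence", MetricSpec("LA", 5), 3, self.CFG)
        b = estimate(six_reader_case, "c1", "confidence", MetricSpec("LA", 5), 3, self.CFG)
        assert a == b

    def test_kernel_agrees_with_enumeration(self, six_reader_case):
        """Vectorized estimator lands within 3 estimated sd of the exact
        enumeration value for every protocol and metric."""
        cfg = BootstrapConfig(n_cycles=100, n_samples=100, n_boots=200,
                              group_sizes=(3,), seed=2)
        for protocol in cc.PROTOCOLS:
            for ms in (MetricSpec("SA"), MetricSpec("LA", 2)):
                exact = cc.exact_average_accuracy(
                    six_reader_case, "c1", protocol, ms, 3
                )
                est = estimate(six_reader_case, "c1", protocol, ms, 3, cfg)
                assert abs(est.mean - exact) <= 3 * max(est.sd, 1e-12), (protocol, ms)

    def test_estimate_bounds_are_sane(self, twelve_reader_case):
        est = estimate(twelve_reader_case, "c", "frequency", MetricSpec("SA"), 3, self.CFG)
        assert 0 <= est.ci_low <= est.median <= est.ci_high <= 1
        assert est.ci_low <= est.mean <= est.ci_high


class TestSweep:
    def test_factorial_cell_count(self):
        ds = make_dataset(
            [("c", ["G"], "easy")],
            [
                (f"r{i}", "c", ["G" if i % 3 else "W"], 1 + i % 6, "recent_graduate")
                for i in range(32)
            ],
        ).validate()
        cfg = BootstrapConfig(n_cycles=5, n_samples=10, n_boots=20,
                              group_sizes=tuple(range(3, 31)), seed=0)
        ests = sweep(ds, cc.PROTOCOLS, (MetricSpec("SA"), MetricSpec("LA", 5)), cfg)
        assert len(ests) == 3 * 2 * 28

    def test_empty_protocol_list_gives_empty_output(self, six_reader_case):
        cfg = BootstrapConfig(n_cycles=2, n_samples=5, n_boots=5, group_sizes=(3,))
        assert sweep(six_reader_case, (), (MetricSpec("SA"),), cfg) == []

    def test_infeasible_sizes_truncated_with_warning(self, six_reader_case, caplog):
        cfg = BootstrapConfig(n_cycles=2, n_samples=5, n_boots=5, group_sizes=(3, 6, 10))
        with caplog.at_level("WARNING"):
            ests = sweep(six_reader_case, ("frequency",), (MetricSpec("SA"),), cfg)
        assert sorted(e.group_size for e in ests) == [3, 6]
        assert "truncating" in caplog.text

    def test_la_dominates_sa_pointwise(self):
        ds = cc.generate(cc.preset("growth", n_readers=60, seed=4))
        cfg = BootstrapConfig(n_cycles=10, n_samples=30, n_boots=30,
                              group_sizes=(3, 10, 25), seed=9)
        ests = sweep(ds, config=cfg)
        df = cc.estimates_table(ests)
        merged = df[df.metric == "LA"].merge(
            df[df.metric == "SA"],
            on=["case_id", "protocol", "group_size"],
            suffixes=("_la", "_sa"),
        )
        assert (merged.mean_la >= merged.mean_sa).all()

    def test_sweep_is_pure_function_of_config(self):
        ds = cc.generate(cc.preset("plateau", n_readers=40, seed=1))
        cfg = BootstrapConfig(n_cycles=5, n_samples=10, n_boots=10, group_sizes=(3, 5))
        assert sweep(ds, config=cfg) == sweep(ds, config=cfg)

    def test_object_path_and_kernel_agree_without_ties(self):
        """On a fixture with a strict confidence hierarchy (no ties ever),
        both implementations of a cycle average estimate the same quantity."""
        ds = make_dataset(
            [("c", ["G"], "easy")],
            [
                ("r0", "c", ["G"], 6, "recent_graduate"),
                ("r1", "c", ["G"], 5, "recent_graduate"),
                ("r2", "c", ["W1"], 3, "recent_graduate"),
                ("r3", "c", ["W2"], 2, "recent_graduate"),
                ("r4", "c", ["W3"], 1, "recent_graduate"),
            ],
        ).validate()
        exact = cc.exact_average_accuracy(ds, "c", "confidence", MetricSpec("SA"), 3)
        obj = cycle_average_accuracy(
            ds, "c", "confidence", MetricSpec("SA"), 3, 5000, np.random.default_rng(0)
        )
        cfg = BootstrapConfig(n_cycles=50, n_samples=100, n_boots=100, group_sizes=(3,))
        kern = estimate(ds, "c", "confidence", MetricSpec("SA"), 3, cfg)
        se = (exact * (1 - exact) / 5000) ** 0.5
        assert abs(obj - exact) < 3 * se
        assert abs(kern.mean - exact) <= 3 * max(kern.sd, 1e-12)


class TestBootstrapConfig:
    def test_rejects_sub_majority_sizes(self):
        with pytest.raises(ConfigError, match="majority"):
            BootstrapConfig(group_sizes=(2, 3))

    def test_rejects_nonpositive_counts(self):
        with pytest.raises(ConfigError):
            BootstrapConfig(n_cycles=0)

    def test_sizes_are_sorted_and_deduplicated(self):
        cfg = BootstrapConfig(group_sizes=(5, 3, 5, 4))
        assert cfg.group_sizes == (3, 4, 5)
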