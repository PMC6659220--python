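"""Classification, entropy cut-off, confusion metrics, and study plumbing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gatedirt import (
    ChainConfig,
    ScenarioConfig,
    best_cutoff_entropy,
    classify,
    confusion_metrics,
    run_simulation_study,
)

TINY_CHAIN = ChainConfig(n_iterations=1500, burn_in=300, thin=3)


def brute_force_entropy_cutoff(p, truth):
    """Independent oracle: scan every midpoint, recompute entropies directly."""
    p = np.asarray(p, float)
    truth = np.asarray(truth)
    uniq = np.unique(p)
    best = (np.inf, None)
    for c in (uniq[:-1] + uniq[1:]) / 2:
        h = 0.0
        for side in (p <= c, p > c):
            n = side.sum()
            if n == 0:
                continue
            q = truth[side].mean()
            ent = 0.0
            for v in (q, 1 - q):
                if v > 0:
                    ent -= v * np.log2(v)
            h += (n / truth.size) * ent
        if h < best[0] - 1e-12 or abs(h - best[0]) <= 1e-12:
            best = (min(h, best[0]), float(c))
    return best[1], best[0]


class TestClassify:
    def test_threshold_examples(self):
        assert list(classify([0.95, 0.5, 0.91], 0.9)) == [1, 0, 1]
        assert list(classify([0.9], 0.9)) == [0]  # strict inequality
        assert list(classify([0.99, 0.5], 0.999)) == [0, 0]

    def test_cutoff_range_enforced(self):
        with pytest.raises(ValueError):
            classify([0.5], 0.0)
        with pytest.raises(ValueError):
            classify([0.5], 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=30),
        st.floats(0.01, 0.99),
    )
    def test_flag_iff_above_cutoff(self, p, cutoff):
        out = classify(p, cutoff)
        assert np.array_equal(out, np.asarray(p) > cutoff)


class TestBestCutoffEntropy:
    def test_perfect_split_at_gap_midpoint(self):
        cut = best_cutoff_entropy([0.1, 0.2, 0.95, 0.99], [0, 0, 1, 1])
        assert cut == pytest.approx(0.575)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            best_cutoff_entropy([0.1, 0.9], [1, 1])

    def test_matches_brute_force_on_random_instances(self, rng):
        """Oracle equivalence over 100 random instances."""
        for _ in range(100):
            n = rng.integers(4, 40)
            p = rng.random(n).round(3)
            truth = rng.integers(0, 2, n)
            if truth.min() == truth.max() or np.unique(p).size < 2:
                continue
            cut = best_cutoff_entropy(p, truth)
            oracle_cut, oracle_h = brute_force_entropy_cutoff(p, truth)
            assert cut == pytest.approx(oracle_cut)

    def test_separable_instances_reach_zero_entropy(self, rng):
        for _ in range(20):
            n0, n1 = rng.integers(2, 15, 2)
            p = np.r_[rng.uniform(0, 0.4, n0), rng.uniform(0.6, 1, n1)]
            truth = np.r_[np.zeros(n0, int), np.ones(n1, int)]
            cut = best_cutoff_entropy(p, truth)
            _, h = brute_force_entropy_cutoff(p, truth)
            assert h == pytest.approx(0.0, abs=1e-12)
            assert p[truth == 0].max() < cut < p[truth == 1].min()

    def test_tie_broken_toward_largest_candidate(self):
        # both candidate splits are equally impure: keep the larger cut-off
        cut = best_cutoff_entropy([0.2, 0.5, 0.8], [1, 0, 1])
        assert cut == pytest.approx(0.65)


class TestConfusionMetrics:
    def test_hand_computed_table(self):
        m = confusion_metrics([1, 0, 0, 0], [1, 1, 0, 0])
        assert m.sensitivity == pytest.approx(0.5)
        assert m.specificity == pytest.approx(1.0)
        assert m.ppv == pytest.approx(1.0)
        assert m.npv == pytest.approx(2 / 3)
        assert m.absolute_agreement == pytest.approx(0.75)
        assert m.apparent_prevalence == pytest.approx(0.25)
        assert m.cohens_kappa == pytest.approx(0.5)

    def test_perfect_and_trivial_classifiers(self):
        truth = np.r_[np.ones(5, int), np.zeros(95, int)]
        perfect = confusion_metrics(truth, truth)
        assert perfect.sensitivity == perfect.specificity == 1.0
        assert perfect.cohens_kappa == pytest.approx(1.0)
        allzero = confusion_metrics(np.zeros(100, int), truth)
        assert allzero.specificity == 1.0
        assert allzero.sensitivity == 0.0
        assert allzero.apparent_prevalence == 0.0

    def test_undefined_ratios_are_nan(self):
        m = confusion_metrics([0, 0], [0, 0])
        assert np.isnan(m.sensitivity) and np.isnan(m.ppv)
        assert m.specificity == 1.0

    def test_kappa_matches_sklearn_on_random_pairs(self, rng):
        from sklearn.metrics import cohen_kappa_score

        for _ in range(1000):
            n = rng.integers(5, 30)
            a = rng.integers(0, 2, n)
            b = rng.integers(0, 2, n)
            ours = confusion_metrics(a, b).cohens_kappa
            theirs = cohen_kappa_score(b, a)
            if np.isnan(ours):
                assert np.isnan(theirs) or theirs in (0.0, 1.0)
            else:
                assert ours == pytest.approx(theirs, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.integers(0, 2**32 - 1))
    def test_ap_identity_exact(self, seed):
        """AP = prev*SEN + (1-prev)*(1-SPE) per confusion table, exactly."""
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 60))
        truth = r.integers(0, 2, n)
        pred = r.integers(0, 2, n)
        if truth.min() == truth.max():
            return
        m = confusion_metrics(pred, truth)
        prev = truth.mean()
        assert m.apparent_prevalence == pytest.approx(
            prev * m.sensitivity + (1 - prev) * (1 - m.specificity), abs=1e-12
        )


class TestRunSimulationStudy:
    @pytest.fixture(scope="class")
    def tiny_study(self):
        scenarios = [
            ScenarioConfig(
                prop_cheaters=0.35, efficacy="high", n_students=40, n_items=30,
                n_exposed=6, n_replicates=3, seed=99,
            ),
            ScenarioConfig(
                prop_cheaters=0.0, efficacy="none", n_students=40, n_items=30,
                n_exposed=6, n_replicates=3, seed=99,
            ),
        ]
        return run_simulation_study(scenarios, chain=TINY_CHAIN, cutoff=0.9)

    def test_summary_layout(self, tiny_study):
        assert list(tiny_study.summary.columns) == ["35-high", "0-none"]
        assert "specificity" in tiny_study.summary.index
        assert "best_cutoff" in tiny_study.summary.index
        assert len(tiny_study.replicates) == 6
        assert tiny_study.excluded == {"35-high": 0, "0-none": 0}

    def test_no_positive_truth_scenario(self, tiny_study):
        """With no cheaters SEN is undefined and AP equals 1 - SPE."""
        col = tiny_study.summary["0-none"]
        assert np.isnan(col["sensitivity"])
        assert col["apparent_prevalence"] == pytest.approx(
            1 - col["specificity"], abs=1e-12
        )

    def test_sd_defined_over_replicates(self, tiny_study):
        assert np.isfinite(tiny_study.sd.loc["specificity", "35-high"])

    def test_deterministic_given_seed(self, tiny_study):
        scen = ScenarioConfig(
            prop_cheaters=0.35, efficacy="high", n_students=40, n_items=30,
            n_exposed=6, n_replicates=2, seed=99,
        )
        a = run_simulation_study([scen], chain=TINY_CHAIN)
        b = run_simulation_study([scen], chain=TINY_CHAIN)
        assert a.summary.equals(b.summary)
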