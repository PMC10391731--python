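import itertools

import numpy as np
import pytest
from scipy import stats

from umiquant import (
    AlleleFamilyCounts,
    AlleleQuantModel,
    activation_prevalence,
    compare_groups,
    mutant_cell_fraction,
)


def counts(wt=0, native=0, active=0):
    return AlleleFamilyCounts(
        "s", {"wt": wt, "ca_native": native, "ca_active": active}
    )


class TestActivationPrevalence:
    def test_simple_ratio(self):
        est = activation_prevalence(counts(native=30, active=10))
        assert est.value == pytest.approx(0.25)
        assert est.ci_low < 0.25 < est.ci_high

    def test_zero_active(self):
        est = activation_prevalence(counts(native=500))
        assert est.value == 0.0

    def test_zero_denominator_missing(self):
        est = activation_prevalence(counts(wt=100))
        assert est.missing
        assert est.reason

    def test_wilson_interval_coverage_at_n_1000(self):
        """Exhaustive coverage of the Wilson interval over a grid of true p."""
        n = 1000
        ks = np.arange(n + 1)
        lows = np.empty(n + 1)
        highs = np.empty(n + 1)
        for k in ks:
            est = activation_prevalence(counts(native=n - k, active=k))
            lows[k], highs[k] = est.ci_low, est.ci_high
        for p in np.linspace(0.02, 0.6, 16):
            pmf = stats.binom.pmf(ks, n, p)
            coverage = pmf[(lows <= p) & (p <= highs)].sum()
            assert coverage >= 0.93


class TestMutantCellFraction:
    def test_simple_ratio(self):
        est = mutant_cell_fraction(counts(wt=10_000, active=50))
        assert est.value == pytest.approx(0.005)
        assert 0 <= est.ci_low <= 0.005 <= est.ci_high

    def test_zero_active(self):
        est = mutant_cell_fraction(counts(wt=100))
        assert est.value == 0.0
        assert est.ci_low == 0.0

    def test_no_wildtype_missing(self):
        est = mutant_cell_fraction(counts(active=5))
        assert est.missing

    def test_interval_contains_estimate(self):
        for wt, active in [(100, 1), (1000, 7), (500, 50)]:
            est = mutant_cell_fraction(counts(wt=wt, active=active))
            assert est.ci_low <= est.value <= est.ci_high


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_shifted_groups_vs_permutation_oracle(self):
        g1 = [1.0, 2.0, 3.0]
        g2 = [11.0, 12.0, 13.0]
        res = compare_groups(g1, g2)
        assert res.p < 0.01
        pooled = g1 + g2
        observed = abs(np.mean(g1) - np.mean(g2))
        diffs = []
        for idx in itertools.combinations(range(6), 3):
            a = [pooled[i] for i in idx]
            b = [pooled[i] for i in range(6) if i not in idx]
            diffs.append(abs(np.mean(a) - np.mean(b)))
        # the observed split is the most extreme of all 20 assignments
        assert observed == pytest.approx(max(diffs))
        assert sum(d >= observed - 1e-12 for d in diffs) == 2

    def test_one_constant_group(self):
        res = compare_groups([5.0, 5.0, 5.0], [1.0, 2.0, 3.0])
        assert not res.degenerate
        assert res.p is not None and res.p < 0.05

    def test_degenerate_zero_variance(self):
        res = compare_groups([2.0, 2.0], [3.0, 3.0])
        assert res.degenerate
        assert res.equal is False
        same = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert same.degenerate and same.equal

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])


class TestModelResults:
    def test_fit_applies_noise_floor(self):
        model = AlleleQuantModel(counts(wt=900, native=700, active=5))
        res = model.fit()
        assert res.counts.reported["ca_active"] == 0
        assert res.activation_prevalence.value == 0.0
        assert res.raw_activation_prevalence.value == pytest.approx(5 / 705)
        assert res.mutant_cell_fraction.value == 0.0
        assert res.raw_mutant_cell_fraction.value == pytest.approx(5 / 900)

    def test_intervals_contain_estimates(self):
        res = AlleleQuantModel(counts(wt=900, native=700, active=40)).fit()
        p = res.activation_prevalence
        assert p.ci_low <= p.value <= p.ci_high
        m = res.mutant_cell_fraction
        assert m.ci_low <= m.value <= m.ci_high

    def test_summary_and_dict(self):
        res = AlleleQuantModel(counts(wt=10, native=8, active=7)).fit()
        text = res.summary()
        assert "activation prevalence" in text and "mutant cell fraction" in text
        d = res.to_dict()
        assert d["counts"]["reported"]["ca_active"] == 7
        assert d["activation_prevalence"]["value"] == pytest.approx(7 / 15)
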