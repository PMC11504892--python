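"""Entropy, MDL discretization and information-gain ranking."""

import itertools
import math

import numpy as np
import pytest

from mirclass.exceptions import ConfigError, DomainError
from mirclass.infogain import (
    InfoGainSelector,
    MDLDiscretizer,
    class_entropy,
    equal_frequency_cutpoints,
    info_gain,
    mdl_discretize,
    select_top,
)
from mirclass.seqio import BINARY, NUMERIC, FeatureTable


def entropy_oracle(labels):
    """Direct formula evaluation, independent of the implementation."""
    n = len(labels)
    h = 0.0
    for c in set(labels):
        p = sum(1 for l in labels if l == c) / n
        h -= p * math.log2(p)
    return h


def make_table(columns, kinds, labels):
    values = np.column_stack([np.asarray(c, dtype=float) for c in columns])
    return FeatureTable(
        ids=[f"i{r}" for r in range(values.shape[0])],
        attributes=[(f"a{j}", kinds[j]) for j in range(values.shape[1])],
        values=values,
        labels=np.asarray(labels, dtype=object),
    )


class TestClassEntropy:
    def test_balanced_binary_is_one_bit(self):
        assert class_entropy(["positive"] * 20 + ["negative"] * 20) == pytest.approx(1.0)

    def test_pure_labels_zero(self):
        assert class_entropy(["positive"] * 7) == 0.0

    def test_30_10_split_matches_formula(self):
        labels = ["positive"] * 30 + ["negative"] * 10
        expected = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert class_entropy(labels) == pytest.approx(expected, abs=1e-12)

    def test_no_labels_rejected(self):
        with pytest.raises(DomainError):
            class_entropy([])


def mdl_first_split_oracle(values, labels):
    """Exhaustive evaluation of every cut position plus the MDL bound.

    Returns the accepted cut value or None; independent re-derivation of
    the Fayyad-Irani acceptance rule for the first (top-level) split.
    """
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    y = np.asarray(labels)[order]
    n = len(v)
    h_s = entropy_oracle(list(y))
    best = None
    for i in range(n - 1):
        if v[i] == v[i + 1]:
            continue
        left, right = list(y[: i + 1]), list(y[i + 1 :])
        gain = h_s - (
            len(left) / n * entropy_oracle(left) + len(right) / n * entropy_oracle(right)
        )
        if best is None or gain > best[0]:
            best = (gain, i, left, right)
    if best is None:
        return None
    gain, i, left, right = best
    k, k1, k2 = len(set(y)), len(set(left)), len(set(right))
    delta = math.log2(3.0**k - 2.0) - (
        k * h_s - k1 * entropy_oracle(left) - k2 * entropy_oracle(right)
    )
    if gain <= (math.log2(n - 1.0) + delta) / n:
        return None
    return (v[i] + v[i + 1]) / 2.0


class TestMDLDiscretize:
    def test_perfectly_separable_single_cut(self):
        cuts = mdl_discretize([1, 2, 3, 4], ["neg", "neg", "pos", "pos"])
        assert len(cuts) == 1
        assert 2 < cuts[0] < 3

    def test_constant_values_no_cut(self):
        assert mdl_discretize([5, 5, 5, 5], ["neg", "pos", "neg", "pos"]) == []

    def test_pure_labels_no_cut(self):
        assert mdl_discretize([1, 2, 3, 4], ["pos"] * 4) == []

    def test_random_labels_mostly_rejected_and_oracle_agrees(self):
        rng = np.random.default_rng(0)
        n_empty = 0
        for _ in range(50):
            values = rng.normal(size=8)
            labels = rng.choice(["pos", "neg"], size=8)
            cuts = mdl_discretize(values, labels)
            oracle_cut = mdl_first_split_oracle(values, labels)
            if oracle_cut is None:
                assert cuts == []
                n_empty += 1
            else:
                assert cuts  # top-level acceptance must agree
                assert oracle_cut in cuts
        assert n_empty > 25  # clear majority rejects under label noise

    def test_cutpoints_sorted(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(-3, 0.3, 30), rng.normal(0, 0.3, 30),
                                 rng.normal(3, 0.3, 30)])
        labels = ["a"] * 30 + ["b"] * 30 + ["a"] * 30
        cuts = mdl_discretize(values, labels)
        assert cuts == sorted(cuts)
        assert len(cuts) >= 2


class TestInfoGain:
    def test_class_copy_attains_class_entropy(self, class_copy_table):
        ranking = info_gain(class_copy_table)
        assert ranking.entries[0] == ("copy", pytest.approx(1.0))
        assert ranking.class_entropy == pytest.approx(1.0)

    def test_constant_attribute_zero_gain(self):
        table = make_table(
            [[1, 1, 1, 1], [7.0, 7.0, 7.0, 7.0]],
            [BINARY, NUMERIC],
            ["positive", "positive", "negative", "negative"],
        )
        gains = info_gain(table).gains()
        assert gains["a1"] == 0.0

    def test_single_class_rejected(self):
        table = make_table([[0, 1]], [BINARY], ["positive", "positive"])
        with pytest.raises(DomainError):
            info_gain(table)

    def test_all_binary_four_instance_toys_match_contingency_oracle(self):
        labels = ["positive", "positive", "negative", "negative"]
        columns = list(itertools.product([0, 1], repeat=4))  # all 2^4 attributes
        table = make_table(columns, [BINARY] * 16, labels)
        ranking = info_gain(table)
        gains = ranking.gains()
        h = entropy_oracle(labels)
        for j, col in enumerate(columns):
            # exhaustive contingency-table computation
            cond = 0.0
            for v in (0, 1):
                sub = [labels[i] for i in range(4) if col[i] == v]
                if sub:
                    cond += len(sub) / 4 * entropy_oracle(sub)
            assert gains[f"a{j}"] == pytest.approx(h - cond, abs=1e-12)

    def test_gain_bounded_by_class_entropy(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            table = make_table(
                [rng.normal(size=30), rng.integers(0, 2, 30)],
                [NUMERIC, BINARY],
                rng.choice(["positive", "negative"], 30),
            )
            if len(set(table.labels)) < 2:
                continue
            ranking = info_gain(table)
            for _, g in ranking.entries:
                assert -1e-9 <= g <= ranking.class_entropy + 1e-9

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        labels = np.where(x + rng.normal(0, 0.5, 40) > 0, "positive", "negative")
        t1 = make_table([x], [NUMERIC], labels)
        t2 = make_table([np.exp(2 * x) - 5], [NUMERIC], labels)  # strictly monotone
        g1 = info_gain(t1).gains()["a0"]
        g2 = info_gain(t2).gains()["a0"]
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_permuted_labels_drive_gain_to_zero(self):
        rng = np.random.default_rng(5)
        n = 40
        labels = np.array(["positive"] * 20 + ["negative"] * 20, dtype=object)
        x = np.where(labels == "positive", rng.normal(1, 1, n), rng.normal(-1, 1, n))

        def gain_of(lab):
            return info_gain(make_table([x], [NUMERIC], lab)).gains()["a0"]

        real = gain_of(labels)
        perms = []
        for _ in range(300):
            perm = labels.copy()
            rng.shuffle(perm)
            perms.append(gain_of(perm))
        perms = np.asarray(perms)
        se = perms.std(ddof=1) / np.sqrt(len(perms))
        assert perms.mean() <= 3 * se
        assert real > perms.mean() + 3 * se  # the true signal stands clear

    def test_ranking_sorted_with_stable_ties(self):
        labels = ["positive", "positive", "negative", "negative"]
        # a0 and a2 tie at gain 1, a1 is uninformative
        table = make_table(
            [[1, 1, 0, 0], [0, 0, 0, 0], [0, 0, 1, 1]],
            [BINARY] * 3,
            labels,
        )
        ranking = info_gain(table)
        assert [n for n, _ in ranking.entries] == ["a0", "a2", "a1"]


class TestSelectTop:
    @pytest.fixture
    def ranking(self, class_copy_table):
        return info_gain(class_copy_table)

    def test_k_one_on_class_copy(self, ranking):
        assert select_top(ranking, k=1) == ["copy"]

    def test_min_gain_zero_keeps_strictly_positive(self):
        labels = ["positive", "positive", "negative", "negative"]
        table = make_table([[1, 1, 0, 0], [1, 1, 1, 1]], [BINARY] * 2, labels)
        assert select_top(info_gain(table), min_gain=0.0) == ["a0"]

    def test_k_too_large_warns_and_returns_all(self, ranking):
        with pytest.warns(UserWarning):
            assert select_top(ranking, k=10) == ["copy"]

    def test_tied_gains_honor_original_order(self):
        labels = ["positive", "positive", "negative", "negative"]
        table = make_table(
            [[1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 0, 0], [0, 1, 0, 1]],
            [BINARY] * 4,
            labels,
        )
        assert select_top(info_gain(table), k=3) == ["a0", "a1", "a2"]

    def test_requires_exactly_one_mode(self, ranking):
        with pytest.raises(ConfigError):
            select_top(ranking)
        with pytest.raises(ConfigError):
            select_top(ranking, k=1, min_gain=0.0)


class TestSklearnEstimators:
    def test_selector_in_isolation(self):
        rng = np.random.default_rng(6)
        y = np.array(["positive"] * 30 + ["negative"] * 30)
        informative = np.where(y == "positive", 1.0, 0.0)
        noise = rng.normal(size=60)
        X = np.column_stack([noise, informative])
        sel = InfoGainSelector(k=1).fit(X, y)
        assert list(sel.get_support()) == [False, True]
        assert sel.gains_[1] == pytest.approx(1.0)
        np.testing.assert_array_equal(sel.transform(X), X[:, [1]])

    def test_selector_min_gain_mode(self):
        y = np.array(["positive"] * 10 + ["negative"] * 10)
        X = np.column_stack([np.where(y == "positive", 1.0, 0.0), np.ones(20)])
        sel = InfoGainSelector(min_gain=0.0).fit(X, y)
        assert list(sel.get_support()) == [True, False]

    def test_discretizer_bins_and_out_of_range(self):
        y = np.array(["neg", "neg", "pos", "pos"])
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        disc = MDLDiscretizer().fit(X, y)
        assert len(disc.cutpoints_[0]) == 1
        out = disc.transform(np.array([[0.0], [2.4], [100.0]]))
        assert out.ravel().tolist() == [0, 0, 1]  # extremes clip into end bins

    def test_equal_frequency_fallback(self):
        values = np.arange(100, dtype=float)
        cuts = equal_frequency_cutpoints(values, bins=4)
        assert len(cuts) == 3
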