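"""Quality functions: frozen examples, invariance properties, sentinels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enetfamily.quality import (
    DEFAULT_QF,
    QF_REGISTRY,
    make_scorer,
    predicted_labels,
    qf_accuracy,
    qf_auc,
    qf_average_accuracy,
    qf_binary_scores,
    qf_correlation,
)


class TestCorrelation:
    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall"])
    def test_identity_and_antiorder(self, method):
        assert qf_correlation([1, 2, 3], [1, 2, 3], method) == pytest.approx(1.0)
        assert qf_correlation([1, 2, 3], [3, 2, 1], method) == pytest.approx(-1.0)

    def test_kendall_single_discordant_pair(self):
        # brute force over the 6 pairs of (1,3,2,4) vs (1,2,3,4):
        # 5 concordant, 1 discordant -> (5-1)/6 = 2/3
        assert qf_correlation([1, 2, 3, 4], [1, 3, 2, 4], "kendall") == pytest.approx(2 / 3)

    def test_zero_variance_is_undefined(self):
        assert math.isnan(qf_correlation([1.0, 1.0, 1.0], [1, 2, 3], "pearson"))
        assert math.isnan(qf_correlation([1, 2, 3], [5.0, 5.0, 5.0], "spearman"))

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            qf_correlation([1, 2, 3], [1, 2, 3], "biweight")


class TestAccuracy:
    def test_fraction_matching(self):
        assert qf_accuracy(list("ABAB"), list("ABBB")) == pytest.approx(0.75)
        assert qf_accuracy(list("AB"), list("AB")) == pytest.approx(1.0)

    def test_average_accuracy_equals_accuracy_for_two_classes(self):
        # one-vs-rest bookkeeping for both classes collapses to 3-of-4 correct
        pred, obs = list("ABAB"), list("ABBB")
        assert qf_average_accuracy(pred, obs) == pytest.approx(qf_accuracy(pred, obs))

    def test_average_accuracy_three_classes(self):
        # per-class one-vs-rest accuracies (3/4, 3/4, 1) -> mean 5/6,
        # confirmed by enumerating the three 2x2 tables
        assert qf_average_accuracy(list("ABBC"), list("AABC")) == pytest.approx(5 / 6)

    def test_perfect_prediction(self):
        assert qf_average_accuracy(list("ABCABC"), list("ABCABC")) == pytest.approx(1.0)

    def test_empty_class_set_rejected(self):
        with pytest.raises(ValueError):
            qf_average_accuracy([], [], classes=[])


class TestBinaryScores:
    def test_confusion_counts(self):
        # TP=2, FP=1, FN=1, TN=1
        obs = ["+", "+", "+", "-", "-"]
        pred = ["+", "+", "-", "+", "-"]
        s = qf_binary_scores(pred, obs, "+")
        assert s["precision"] == pytest.approx(2 / 3)
        assert s["recall"] == pytest.approx(2 / 3)
        assert s["fscore"] == pytest.approx(2 / 3)
        assert s["specificity"] == pytest.approx(1 / 2)

    def test_perfect_prediction_all_ones(self):
        s = qf_binary_scores(list("++--"), list("++--"), "+")
        assert all(v == pytest.approx(1.0) for v in s.values())

    def test_all_predicted_negative(self):
        s = qf_binary_scores(list("----"), list("++--"), "+")
        assert math.isnan(s["precision"])
        assert s["recall"] == 0.0


class TestAUC:
    def test_perfect_separation(self):
        assert qf_auc([0.9, 0.8, 0.3, 0.2], list("++--"), "+") == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        assert qf_auc([0.5] * 4, list("++--"), "+") == pytest.approx(0.5)

    def test_three_wins_one_loss(self):
        # pairs: (.9,.6)+, (.9,.2)+, (.4,.6)-, (.4,.2)+ -> 3/4
        assert qf_auc([0.9, 0.4, 0.6, 0.2], list("++--"), "+") == pytest.approx(0.75)

    def test_single_class_undefined(self):
        assert math.isnan(qf_auc([0.1, 0.9], list("++"), "+"))

    def test_matches_pairwise_enumeration(self, rng):
        scores = rng.normal(size=30)
        obs = rng.choice(["+", "-"], size=30)
        if len(set(obs)) < 2:
            obs[0], obs[1] = "+", "-"
        pos = scores[obs == "+"]
        neg = scores[obs == "-"]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert qf_auc(scores, obs, "+") == pytest.approx(wins / (len(pos) * len(neg)))


@settings(derandomize=True, max_examples=60)
@given(
    data=st.data(),
    n=st.integers(min_value=4, max_value=30),
    k=st.integers(min_value=2, max_value=4),
)
def test_label_permutation_invariance(data, n, k):
    """Accuracy and average accuracy are invariant under any simultaneous
    bijection of class labels applied to predictions and observations."""
    labels = list(range(k))
    pred = data.draw(st.lists(st.sampled_from(labels), min_size=n, max_size=n))
    obs = data.draw(st.lists(st.sampled_from(labels), min_size=n, max_size=n))
    perm = data.draw(st.permutations(labels))
    mapped_pred = [perm[v] for v in pred]
    mapped_obs = [perm[v] for v in obs]
    assert qf_accuracy(mapped_pred, mapped_obs) == pytest.approx(qf_accuracy(pred, obs))
    assert qf_average_accuracy(mapped_pred, mapped_obs, classes=labels) == pytest.approx(
        qf_average_accuracy(pred, obs, classes=labels)
    )


def test_noninvariant_measures_change_under_label_swap():
    """Precision, recall, F1, specificity and AUC all differ under a class
    swap on at least one instance (they are not label-permutation invariant)."""
    obs = ["+", "+", "+", "-", "-"]
    pred = ["+", "+", "-", "+", "-"]
    scores = [0.9, 0.8, 0.4, 0.6, 0.2]
    swap = {"+": "-", "-": "+"}
    s = qf_binary_scores(pred, obs, "+")
    s_swapped = qf_binary_scores([swap[v] for v in pred], [swap[v] for v in obs], "+")
    changed = [k for k in s if not np.isclose(s[k], s_swapped[k], equal_nan=True)]
    assert set(changed) == {"precision", "recall", "fscore", "specificity"}
    auc = qf_auc(scores, obs, "+")
    auc_swapped = qf_auc(scores, [swap[v] for v in obs], "+")
    assert not np.isclose(auc, auc_swapped)


@settings(derandomize=True, max_examples=40)
@given(data=st.data(), n=st.integers(min_value=5, max_value=25))
def test_qf_ranges_on_random_inputs(data, n):
    pred = data.draw(st.lists(st.sampled_from([0, 1]), min_size=n, max_size=n))
    obs = data.draw(st.lists(st.sampled_from([0, 1]), min_size=n, max_size=n))
    assert 0.0 <= qf_accuracy(pred, obs) <= 1.0
    assert 0.0 <= qf_average_accuracy(pred, obs, classes=[0, 1]) <= 1.0
    scores = data.draw(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=n, max_size=n)
    )
    auc = qf_auc(scores, obs, 1)
    assert math.isnan(auc) or 0.0 <= auc <= 1.0


class TestScorerResolution:
    def test_family_defaults(self):
        assert DEFAULT_QF == {
            "linear": "correlation",
            "binomial": "accuracy",
            "multinomial": "average_accuracy",
        }

    def test_default_scorers_match_direct_functions(self):
        lin = make_scorer("linear")
        assert lin([1.0, 2.0, 3.0], [1.0, 2.5, 2.9]) == pytest.approx(
            qf_correlation([1, 2, 3], [1, 2.5, 2.9], "pearson")
        )
        prob = np.array([[0.2, 0.8], [0.6, 0.4], [0.9, 0.1]])
        obs = np.array([1, 0, 1])
        binom = make_scorer("binomial", classes=["a", "b"])
        assert binom(prob, obs) == pytest.approx(2 / 3)

    def test_binomial_tie_goes_to_first_class(self):
        prob = np.array([[0.5, 0.5]])
        assert predicted_labels(prob, "binomial")[0] == 0

    def test_wrong_family_rejected(self):
        with pytest.raises(ValueError):
            make_scorer("linear", "accuracy")
        with pytest.raises(KeyError):
            make_scorer("linear", "nonsense")

    def test_user_callable_passes_through(self):
        fn = lambda pred, obs: 0.42
        assert make_scorer("linear", fn)([1], [2]) == 0.42

    def test_registry_invariance_metadata(self):
        assert QF_REGISTRY["accuracy"].label_permutation_invariant
        assert QF_REGISTRY["average_accuracy"].label_permutation_invariant
        assert not QF_REGISTRY["auc"].label_permutation_invariant
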