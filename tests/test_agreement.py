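"""Agreement statistics: weights, pa/pe, AC1, missing data, variance."""

import numpy as np
import pandas as pd
import pytest

from schroth_agree import (
    RatingMatrix,
    WeightMatrix,
    chance_agreement,
    gwet_ac,
    identity_weights,
    inter_rater,
    intra_rater,
    observed_agreement,
    percent_agreement,
    schroth_weights,
)
from schroth_agree.agreement import DegenerateRatingsError

from conftest import make_matrix, pairwise_observed_agreement, random_small_matrix


# ---------------------------------------------------------------- weights


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("3c", "3c", 1.00),
        ("3c", "3cp", 0.75),
        ("3c", "4c", 0.50),
        ("3c", "4cp", 0.00),
        ("3cp", "4c", 0.00),
        ("3cp", "4cp", 0.00),
        ("4c", "4cp", 0.75),
    ],
)
def test_schroth_weight_entries(a, b, expected):
    w = schroth_weights()
    assert w.lookup(a, b) == expected
    assert w.lookup(b, a) == expected  # symmetry


def test_identity_weights_shapes():
    assert np.array_equal(identity_weights(4).values, np.eye(4))
    assert np.array_equal(identity_weights(2).values, np.eye(2))
    with pytest.raises(ValueError):
        identity_weights(1)


@pytest.mark.parametrize(
    "values, message",
    [
        (np.array([[1.0, 0.5], [0.4, 1.0]]), "symmetric"),
        (np.array([[0.9, 0.5], [0.5, 1.0]]), "diagonal"),
        (np.array([[1.0, 1.5], [1.5, 1.0]]), r"\[0, 1\]"),
    ],
)
def test_weight_matrix_validation(values, message):
    with pytest.raises(ValueError, match=message):
        WeightMatrix(values, ("a", "b"))


# --------------------------------------------------- observed agreement


def test_identical_raters_give_full_agreement(q4):
    m = make_matrix({"A": ["3c"] * 5, "B": ["3c", "3cp", "4c", "4cp", "3c"]}, q4)
    perfect = make_matrix(
        {"A": ["3c", "3cp", "4c", "4cp", "3c"], "B": ["3c", "3cp", "4c", "4cp", "3c"]},
        q4,
    )
    assert observed_agreement(perfect, identity_weights(q4)) == 1.0
    assert observed_agreement(m, identity_weights(q4)) < 1.0


def test_four_subject_half_agreement_binary():
    cats = ("c1", "c2")
    m = make_matrix({"A": ["c1", "c1", "c2", "c2"], "B": ["c1", "c2", "c2", "c1"]}, cats)
    assert observed_agreement(m, identity_weights(cats)) == pytest.approx(0.5)


def test_single_pair_partial_credit(q4):
    m = make_matrix({"A": ["3c"], "B": ["3cp"]}, q4)
    assert observed_agreement(m, schroth_weights()) == pytest.approx(0.75)


def test_observed_agreement_requires_a_rated_pair(q4):
    m = make_matrix({"A": ["3c", "3cp"], "B": [None, None]}, q4)
    with pytest.raises(DegenerateRatingsError):
        observed_agreement(m, identity_weights(q4))


# ----------------------------------------------------- chance agreement


def test_chance_agreement_binary_balanced():
    cats = ("c1", "c2")
    m = make_matrix({"A": ["c1", "c1", "c2", "c2"], "B": ["c1", "c2", "c2", "c1"]}, cats)
    assert chance_agreement(m, identity_weights(cats)) == pytest.approx(0.5)


def test_chance_agreement_single_category_is_zero(q4):
    m = make_matrix({"A": ["3c"] * 4, "B": ["3c"] * 4}, q4)
    assert chance_agreement(m, identity_weights(q4)) == pytest.approx(0.0)


def test_chance_agreement_hand_computed_quartic(q4):
    # propensities (0.25, 0.25, 0.375, 0.125) -> pe = 0.2395833...
    m = make_matrix(
        {"A": ["3c", "3cp", "4c", "4cp"], "B": ["3c", "3cp", "4c", "4c"]}, q4
    )
    assert chance_agreement(m, identity_weights(q4)) == pytest.approx(
        0.2395833333, abs=1e-9
    )


# ------------------------------------------------------------ gwet_ac


def test_perfect_agreement_coefficient_is_one(q4):
    m = make_matrix(
        {"A": ["3c", "3cp", "4c", "4cp"], "B": ["3c", "3cp", "4c", "4cp"]}, q4
    )
    res = gwet_ac(m, identity_weights(q4))
    assert res.estimate == pytest.approx(1.0)
    assert res.ci_high <= 1.0


def test_zero_coefficient_when_pa_equals_pe():
    cats = ("c1", "c2")
    m = make_matrix({"A": ["c1", "c1", "c2", "c2"], "B": ["c1", "c2", "c2", "c1"]}, cats)
    res = gwet_ac(m, identity_weights(cats))
    assert res.pa == pytest.approx(0.5)
    assert res.pe == pytest.approx(0.5)
    assert res.estimate == pytest.approx(0.0, abs=1e-12)


def test_hand_computed_quartic_coefficient(q4):
    m = make_matrix(
        {"A": ["3c", "3cp", "4c", "4cp"], "B": ["3c", "3cp", "4c", "4c"]}, q4
    )
    res = gwet_ac(m, identity_weights(q4))
    assert res.pa == pytest.approx(0.75)
    assert res.estimate == pytest.approx(0.67123, abs=1e-5)


def test_degenerate_single_category_raises():
    cats = ("c1", "c2")
    # pe = 1 requires propensity concentration impossible with q>=2 unless
    # weights make T_w large; the practical degenerate case is no rated pair
    m = make_matrix({"A": [None, None], "B": ["c1", "c2"]}, cats)
    with pytest.raises(DegenerateRatingsError):
        gwet_ac(m, identity_weights(cats))


# ---------------------------------------------------- oracle equivalence


def test_pa_formula_matches_pairwise_enumeration_oracle(q4):
    rng = np.random.default_rng(20260922)
    weights = [identity_weights(q4), schroth_weights()]
    for _ in range(200):
        m = random_small_matrix(rng)
        for w in weights:
            assert observed_agreement(m, w) == pytest.approx(
                pairwise_observed_agreement(m, w), abs=1e-12
            )


def test_identity_weights_reduce_to_unweighted(q4):
    rng = np.random.default_rng(42)
    for _ in range(50):
        m = random_small_matrix(rng)
        unweighted = gwet_ac(m)  # default identity
        explicit = gwet_ac(m, identity_weights(q4))
        assert unweighted.estimate == explicit.estimate
        assert unweighted.pa == explicit.pa
        assert unweighted.pe == explicit.pe


def test_permutation_invariance(q4):
    rng = np.random.default_rng(7)
    for _ in range(20):
        m = random_small_matrix(rng)
        res = gwet_ac(m, schroth_weights())
        shuffled_subjects = RatingMatrix(
            m.frame.sample(frac=1, random_state=3), q4
        )
        reversed_raters = RatingMatrix(m.frame[m.frame.columns[::-1]], q4)
        assert gwet_ac(shuffled_subjects, schroth_weights()).estimate == (
            pytest.approx(res.estimate, abs=1e-12)
        )
        assert gwet_ac(reversed_raters, schroth_weights()).estimate == (
            pytest.approx(res.estimate, abs=1e-12)
        )


# ----------------------------------------------------------- variance


def test_jackknife_se_positive_under_disagreement(q4):
    m = make_matrix(
        {"A": ["3c", "3cp", "4c", "4cp", "3c", "4c"],
         "B": ["3c", "4c", "4c", "3cp", "3c", "4cp"]},
        q4,
    )
    res = gwet_ac(m, identity_weights(q4))
    assert res.se > 0
    assert res.ci_low <= res.estimate <= res.ci_high


def test_jackknife_se_shrinks_as_root_n(q4):
    base = make_matrix(
        {"A": ["3c", "3cp", "4c", "4cp", "3c", "4c", "3cp", "4cp"],
         "B": ["3c", "4c", "4c", "3cp", "3c", "4cp", "3cp", "4cp"]},
        q4,
    )
    doubled = RatingMatrix(
        pd.concat([base.frame, base.frame], ignore_index=True), q4
    )
    se1 = gwet_ac(base, identity_weights(q4)).se
    se2 = gwet_ac(doubled, identity_weights(q4)).se
    assert 0.6 < se2 / se1 * np.sqrt(2) < 1.3


def test_ci_upper_truncated_at_one(q4):
    # near-perfect agreement with tiny n: untruncated CI would exceed 1
    m = make_matrix(
        {"A": ["3c", "3cp", "4c", "4cp", "3c"], "B": ["3c", "3cp", "4c", "4cp", "4c"]},
        q4,
    )
    res = gwet_ac(m, identity_weights(q4))
    assert res.ci_high <= 1.0


# ------------------------------------------------- intra- / inter-rater


def _occasions(col1, col2, q4):
    t1 = make_matrix({"r1": col1}, q4)
    t2 = make_matrix({"r1": col2}, q4)
    return t1, t2


def test_intra_rater_perfect_repeat(q4):
    labels = ["3c", "3cp", "4c", "4cp"] * 3
    t1, t2 = _occasions(labels, list(labels), q4)
    assert intra_rater(t1, t2, "r1").estimate == pytest.approx(1.0)


def test_intra_rater_37_of_44(q4):
    # 37 repeats out of 44: raw percent agreement 84.1%
    labels = (["3c"] * 11 + ["3cp"] * 11 + ["4c"] * 11 + ["4cp"] * 11)
    second = list(labels)
    flips = {0: "3cp", 5: "4c", 12: "3c", 18: "4cp", 23: "3c", 30: "4cp", 40: "4c"}
    for idx, new in flips.items():
        second[idx] = new
    t1, t2 = _occasions(labels, second, q4)
    res = intra_rater(t1, t2, "r1")
    assert res.pa == pytest.approx(37 / 44, abs=1e-12)


def test_intra_rater_excludes_incomplete_pairs_from_pa(q4):
    labels = ["3c", "3cp", "4c", "4cp", "3c"]
    second = ["3c", "3cp", "4c", "4cp", None]
    t1, t2 = _occasions(labels, second, q4)
    res = intra_rater(t1, t2, "r1")
    assert res.pa == pytest.approx(1.0)
    assert res.n_subjects_used == 4


def test_intra_rater_errors(q4):
    t1, t2 = _occasions(["3c", "3cp"], [None, None], q4)
    with pytest.raises(DegenerateRatingsError, match="fewer than 2"):
        intra_rater(t1, t2, "r1")
    with pytest.raises(KeyError):
        intra_rater(t1, t2, "missing_rater")


def test_inter_rater_identical_panel(q4):
    col = ["3c", "3cp", "4c", "4cp", "3c"]
    m = make_matrix({f"r{i}": list(col) for i in range(10)}, q4)
    assert inter_rater(m).estimate == pytest.approx(1.0)


def test_inter_rater_three_raters_pair_enumeration(q4):
    m = make_matrix({"A": ["3c", "3cp"], "B": ["3c", "3cp"], "C": ["3cp", "3cp"]}, q4)
    # subject 1: 1 of 3 pairs agree; subject 2: all 3 agree
    assert observed_agreement(m, identity_weights(q4)) == pytest.approx(
        (1 / 3 + 1.0) / 2
    )
    with pytest.raises(ValueError, match=">= 2 raters"):
        inter_rater(make_matrix({"A": ["3c", "3cp"]}, q4))


def test_percent_agreement_has_no_chance_correction(q4):
    m = make_matrix(
        {"A": ["3c", "3cp", "4c", "4cp"], "B": ["3c", "3cp", "4c", "4c"]}, q4
    )
    res = percent_agreement(m, identity_weights(q4))
    assert res.estimate == pytest.approx(0.75)
    assert res.pe == 0.0
    assert res.se > 0


def test_category_mismatch_rejected(q4):
    m = make_matrix({"A": ["3c", "3cp"], "B": ["3c", "3c"]}, q4)
    with pytest.raises(ValueError, match="do not match"):
        observed_agreement(m, identity_weights(("a", "b", "c", "d")))
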