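"""Shared fixtures and the independent pairwise-enumeration oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from schroth_agree import RatingMatrix, WeightMatrix


def make_matrix(columns: dict[str, list], categories) -> RatingMatrix:
    """Build a RatingMatrix from rater -> ratings lists (None = missing)."""
    frame = pd.DataFrame(
        {k: pd.Series(v, dtype=object) for k, v in columns.items()}
    )
    frame = frame.where(frame.notna(), np.nan)
    return RatingMatrix(frame, categories)


def pairwise_observed_agreement(
    matrix: RatingMatrix, weights: WeightMatrix
) -> float:
    """Independent oracle for observed agreement.

    Averages the weight of every unordered pair of non-missing ratings
    within each subject, then averages over subjects with >= 2 ratings.
    Deliberately naive: no count vectors, no linear algebra.
    """
    per_subject = []
    for _, row in matrix.frame.iterrows():
        labels = [v for v in row if isinstance(v, str)]
        if len(labels) < 2:
            continue
        pair_weights = [
            weights.lookup(a, b) for a, b in itertools.combinations(labels, 2)
        ]
        per_subject.append(sum(pair_weights) / len(pair_weights))
    if not per_subject:
        raise ValueError("oracle: no subject with >= 2 ratings")
    return sum(per_subject) / len(per_subject)


def random_small_matrix(
    rng: np.random.Generator, categories=("3c", "3cp", "4c", "4cp")
) -> RatingMatrix:
    """Random matrix with <= 5 subjects, <= 3 raters, random missingness,
    guaranteed to contain at least one subject with >= 2 ratings."""
    while True:
        n = rng.integers(1, 6)
        r = rng.integers(2, 4)
        labels = np.array(categories, dtype=object)[
            rng.integers(0, len(categories), size=(n, r))
        ]
        mask = rng.random((n, r)) < 0.25
        labels = labels.astype(object)
        labels[mask] = np.nan
        frame = pd.DataFrame(
            labels, columns=[f"rater{j}" for j in range(r)]
        )
        if (frame.notna().sum(axis=1) >= 2).any():
            return RatingMatrix(frame, categories)


@pytest.fixture
def q4():
    return ("3c", "3cp", "4c", "4cp")
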