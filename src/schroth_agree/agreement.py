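"""Chance-corrected multi-rater agreement statistics (Gwet's AC1 family).

Implements percent agreement, Gwet's AC1, and its weighted
generalisation for an arbitrary partial-credit weight matrix, on a
subjects x raters table of categorical ratings with missing values.

Notation
--------
For subject ``i`` let ``r_ik`` be the number of raters who placed the
subject in category ``k`` and ``r_i = sum_k r_ik`` the number of
non-missing ratings.  With weights ``w_kl`` and
``r*_ik = sum_l w_kl r_il``, observed (weighted) agreement is the
average over subjects with at least two ratings of

    p_a,i = sum_k r_ik (r*_ik - 1) / (r_i (r_i - 1)).

Chance agreement uses the category propensities
``pi_k = (1/n) sum_i r_ik / r_i`` and

    p_e = (T_w / (q (q - 1))) * sum_k pi_k (1 - pi_k),

where ``T_w`` is the sum of all weights (``T_w = q`` for identity
weights, recovering unweighted AC1).  The coefficient is
``AC = (p_a - p_e) / (1 - p_e)``.

Subjects rated fewer than twice are excluded from ``p_a`` but their
available ratings still inform ``pi_k``.  Standard errors come from a
subject-level delete-one jackknife; 95% confidence intervals are normal
approximations with the upper bound truncated at 1.

The unweighted coefficient is exactly the weighted pipeline run with an
identity weight matrix: AC1 is robust to the prevalence paradoxes that
make Cohen/Fleiss kappa misleading for skewed category distributions,
which is why it is the coefficient of choice for clinical
classification studies with uneven curve-type prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import CATEGORIES

__all__ = [
    "WeightMatrix",
    "RatingMatrix",
    "AgreementResult",
    "schroth_weights",
    "identity_weights",
    "observed_agreement",
    "chance_agreement",
    "gwet_ac",
    "intra_rater",
    "inter_rater",
]

Z_95 = 1.96

#: Partial-agreement weights over (3c, 3cp, 4c, 4cp).  Clinically similar
#: pairs (same major-curve group, differing only in pelvis involvement)
#: receive 0.75; 3c/4c share a balanced pelvis and similar prescriptions
#: (0.50); pairs whose treatments act in opposite directions or on
#: different body regions receive no credit.
_SCHROTH_WEIGHTS = np.array(
    [
        [1.00, 0.75, 0.50, 0.00],
        [0.75, 1.00, 0.00, 0.00],
        [0.50, 0.00, 1.00, 0.75],
        [0.00, 0.00, 0.75, 1.00],
    ]
)


@dataclass(frozen=True)
class WeightMatrix:
    """Symmetric q x q partial-credit matrix with unit diagonal."""

    values: np.ndarray
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", w)
        q = len(self.categories)
        if w.shape != (q, q):
            raise ValueError(f"weight matrix shape {w.shape} != ({q}, {q})")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if not np.allclose(np.diag(w), 1.0):
            raise ValueError("weight matrix diagonal must be 1.0")
        if w.min() < 0 or w.max() > 1:
            raise ValueError("weights must lie in [0, 1]")

    @property
    def q(self) -> int:
        return len(self.categories)

    @property
    def total_weight(self) -> float:
        """T_w, the sum of all entries."""
        return float(self.values.sum())

    def lookup(self, a: str, b: str) -> float:
        return float(
            self.values[self.categories.index(a), self.categories.index(b)]
        )

    def is_identity(self) -> bool:
        return bool(np.array_equal(self.values, np.eye(self.q)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.categories, columns=self.categories
        )


def schroth_weights() -> WeightMatrix:
    """The default partial-agreement weights for the four curve types."""
    return WeightMatrix(_SCHROTH_WEIGHTS.copy(), CATEGORIES)


def identity_weights(q: int | Sequence[str] = CATEGORIES) -> WeightMatrix:
    """Identity weights: full credit for exact matches only.

    ``q`` may be a category list or a count >= 2 (categories are then
    auto-named ``c1..cq``).
    """
    if isinstance(q, int):
        if q < 2:
            raise ValueError("need at least 2 categories")
        cats: tuple[str, ...] = tuple(f"c{i + 1}" for i in range(q))
    else:
        cats = tuple(q)
        if len(cats) < 2:
            raise ValueError("need at least 2 categories")
    return WeightMatrix(np.eye(len(cats)), cats)


class RatingMatrix:
    """Subjects x raters categorical ratings, missing values allowed.

    Wraps a pandas DataFrame (index: subject ids, columns: rater ids,
    cells: category labels or NaN) together with the fixed category
    list.  The category list — not the categories actually used — fixes
    ``q`` for chance-agreement purposes.
    """

    def __init__(
        self,
        ratings: pd.DataFrame,
        categories: Sequence[str] = CATEGORIES,
        occasion: int | None = None,
    ) -> None:
        self.categories = tuple(categories)
        self.occasion = occasion
        frame = ratings.copy()
        bad = set(frame.stack().unique()) - set(self.categories)
        if bad:
            raise ValueError(
                f"ratings contain undeclared categories: {sorted(bad)}"
            )
        self.frame = frame

    # -- construction ---------------------------------------------------

    @classmethod
    def from_long(
        cls,
        table: pd.DataFrame,
        categories: Sequence[str] = CATEGORIES,
        occasion: int | None = None,
    ) -> "RatingMatrix":
        """Build from long format (subject_id, rater_id, rating)."""
        wide = table.pivot(
            index="subject_id", columns="rater_id", values="rating"
        )
        return cls(wide, categories, occasion)

    # -- basic accessors ------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.frame.shape[0]

    @property
    def n_raters(self) -> int:
        return self.frame.shape[1]

    @property
    def q(self) -> int:
        return len(self.categories)

    def counts(self) -> np.ndarray:
        """r_ik: n_subjects x q matrix of per-category rating counts."""
        n, q = self.n_subjects, self.q
        out = np.zeros((n, q), dtype=float)
        values = self.frame.to_numpy(dtype=object)
        index = {c: k for k, c in enumerate(self.categories)}
        for i in range(n):
            for v in values[i]:
                if isinstance(v, str):
                    out[i, index[v]] += 1
        return out

    def subset_subjects(self, mask: np.ndarray) -> "RatingMatrix":
        return RatingMatrix(self.frame.iloc[mask], self.categories, self.occasion)


@dataclass
class AgreementResult:
    """One agreement coefficient with its components and uncertainty."""

    estimate: float
    pa: float
    pe: float
    se: float
    ci_low: float
    ci_high: float
    n_subjects_used: int
    n_raters: int
    weighted: bool
    label: str = ""

    def __post_init__(self) -> None:
        if self.pe < 1 and not math.isclose(
            self.estimate, (self.pa - self.pe) / (1 - self.pe), abs_tol=1e-9
        ):
            raise ValueError("estimate inconsistent with (pa-pe)/(1-pe)")


class DegenerateRatingsError(ValueError):
    """Raised when the coefficient is undefined (pe = 1 or too few data)."""


def _components(
    r_ik: np.ndarray, weights: WeightMatrix
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Return (pa, pe, per-subject pa terms, usable-subject mask)."""
    r_i = r_ik.sum(axis=1)
    usable = r_i >= 2
    if not usable.any():
        raise DegenerateRatingsError(
            "no subject has >= 2 ratings; agreement is undefined"
        )
    w = weights.values
    q = weights.q
    # r*_ik = sum_l w_kl r_il
    r_star = r_ik @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        pa_i = np.where(
            usable,
            (r_ik * (r_star - 1)).sum(axis=1)
            / np.where(usable, r_i * (r_i - 1), 1.0),
            0.0,
        )
    pa = float(pa_i[usable].mean())
    # propensities use every subject with at least one rating
    rated = r_i >= 1
    pi_k = (r_ik[rated] / r_i[rated, None]).mean(axis=0)
    pe = float(weights.total_weight / (q * (q - 1)) * (pi_k * (1 - pi_k)).sum())
    return pa, pe, pa_i, usable


def observed_agreement(ratings: RatingMatrix, weights: WeightMatrix) -> float:
    """Observed (possibly weighted) agreement p_a."""
    _check_compatible(ratings, weights)
    pa, _, _, _ = _components(ratings.counts(), weights)
    return pa


def chance_agreement(ratings: RatingMatrix, weights: WeightMatrix) -> float:
    """Chance (possibly weighted) agreement p_e."""
    _check_compatible(ratings, weights)
    _, pe, _, _ = _components(ratings.counts(), weights)
    return pe


def _check_compatible(ratings: RatingMatrix, weights: WeightMatrix) -> None:
    if ratings.categories != weights.categories:
        raise ValueError(
            "rating categories do not match weight-matrix categories: "
            f"{ratings.categories} vs {weights.categories}"
        )


def _point_estimate(r_ik: np.ndarray, weights: WeightMatrix) -> float:
    pa, pe, _, _ = _components(r_ik, weights)
    if pe >= 1:
        raise DegenerateRatingsError("chance agreement is 1; AC undefined")
    return (pa - pe) / (1 - pe)


def _jackknife_se(r_ik: np.ndarray, weights: WeightMatrix) -> float:
    """Subject-level delete-one jackknife standard error of the AC."""
    n = r_ik.shape[0]
    if n < 2:
        return float("nan")
    estimates = []
    for i in range(n):
        sub = np.delete(r_ik, i, axis=0)
        try:
            estimates.append(_point_estimate(sub, weights))
        except DegenerateRatingsError:
            return float("nan")
    theta = np.array(estimates)
    return float(np.sqrt((n - 1) / n * ((theta - theta.mean()) ** 2).sum()))


def gwet_ac(
    ratings: RatingMatrix, weights: WeightMatrix | None = None, label: str = ""
) -> AgreementResult:
    """Gwet's (weighted) agreement coefficient with jackknife CI.

    With identity weights (the default) this is the unweighted AC1;
    any other symmetric unit-diagonal matrix gives the weighted
    generalisation (AC2 in Gwet's terminology).
    """
    if weights is None:
        weights = identity_weights(ratings.categories)
    _check_compatible(ratings, weights)
    r_ik = ratings.counts()
    pa, pe, _, usable = _components(r_ik, weights)
    if pe >= 1:
        raise DegenerateRatingsError("chance agreement is 1; AC undefined")
    estimate = (pa - pe) / (1 - pe)
    se = _jackknife_se(r_ik, weights)
    if math.isnan(se):
        ci_low = ci_high = float("nan")
    else:
        ci_low = estimate - Z_95 * se
        ci_high = min(estimate + Z_95 * se, 1.0)
    return AgreementResult(
        estimate=estimate,
        pa=pa,
        pe=pe,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_subjects_used=int(usable.sum()),
        n_raters=ratings.n_raters,
        weighted=not weights.is_identity(),
        label=label,
    )


def percent_agreement(
    ratings: RatingMatrix, weights: WeightMatrix | None = None, label: str = ""
) -> AgreementResult:
    """Observed agreement alone, with jackknife CI (no chance correction)."""
    if weights is None:
        weights = identity_weights(ratings.categories)
    _check_compatible(ratings, weights)
    r_ik = ratings.counts()
    pa, _, _, usable = _components(r_ik, weights)
    n = r_ik.shape[0]
    if n >= 2:
        thetas = []
        for i in range(n):
            sub = np.delete(r_ik, i, axis=0)
            try:
                thetas.append(_components(sub, weights)[0])
            except DegenerateRatingsError:
                thetas = []
                break
        if thetas:
            t = np.array(thetas)
            se = float(np.sqrt((n - 1) / n * ((t - t.mean()) ** 2).sum()))
        else:
            se = float("nan")
    else:
        se = float("nan")
    ci_low = pa - Z_95 * se if not math.isnan(se) else float("nan")
    ci_high = min(pa + Z_95 * se, 1.0) if not math.isnan(se) else float("nan")
    return AgreementResult(
        estimate=pa,
        pa=pa,
        pe=0.0,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_subjects_used=int(usable.sum()),
        n_raters=ratings.n_raters,
        weighted=not weights.is_identity(),
        label=label,
    )


def intra_rater(
    ratings_t1: RatingMatrix,
    ratings_t2: RatingMatrix,
    rater: object,
    weights: WeightMatrix | None = None,
) -> AgreementResult:
    """Test-retest agreement of one rater across the two occasions.

    The rater's occasion-1 and occasion-2 columns form a two-"rater"
    matrix; subjects missing either rating drop out of p_a (they retain
    their single rating for the propensities).
    """
    for m in (ratings_t1, ratings_t2):
        if rater not in m.frame.columns:
            raise KeyError(f"rater {rater!r} not present in both occasions")
    if ratings_t1.categories != ratings_t2.categories:
        raise ValueError("occasions declare different category lists")
    pair = pd.DataFrame(
        {
            "occasion_1": ratings_t1.frame[rater],
            "occasion_2": ratings_t2.frame[rater],
        }
    )
    both = pair.notna().all(axis=1).sum()
    if both < 2:
        raise DegenerateRatingsError(
            f"rater {rater!r} rated fewer than 2 subjects on both occasions"
        )
    matrix = RatingMatrix(pair, ratings_t1.categories)
    return gwet_ac(matrix, weights, label=str(rater))


def inter_rater(
    ratings: RatingMatrix, weights: WeightMatrix | None = None, label: str = ""
) -> AgreementResult:
    """Multi-rater agreement among all raters at one occasion."""
    if ratings.n_raters < 2:
        raise ValueError("inter-rater agreement needs >= 2 raters")
    return gwet_ac(ratings, weights, label=label)
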