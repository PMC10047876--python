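"""Generative model of a two-occasion multi-rater classification study.

Emulates the design of a Schroth curve-type reliability study: a fixed
panel of subjects, each with a true curve type drawn from a prevalence
vector; a heterogeneous panel of raters who classify every subject on
two occasions at least a week apart; occasional missing ratings.

Rater model
-----------
Each rater has three parameters:

* ``accuracy`` a — probability of assigning the true category on a
  fresh look;
* ``consistency`` c — probability the occasion-2 label simply copies
  the occasion-1 label (memory/stable judgement); otherwise the rater
  takes a fresh, independent look;
* ``missing_rate`` — probability any single rating is absent.

Errors are not uniform across categories: a rater who misses spreads
the error mass over the other categories in proportion to their
clinical similarity to the truth (the partial-agreement weights, with a
small floor so every confusion remains possible).  This encodes that
3c/3cp and 4c/4cp are confusable while opposite-treatment pairs are
rarely interchanged.  The resulting row-stochastic confusion matrix has
``C[t,t] = a`` and, for k != t,

    C[t,k] = (1 - a) * w'_tk / sum_{l != t} w'_tl,

where ``w'`` is the weight matrix with zeros floored at 0.05.

The model admits a closed form for the expected intra-rater raw
agreement, used as the oracle in parameter-recovery checks:

    E[pa] = sum_t pi_t [ c + (1 - c) sum_k C[t,k]^2 ].

Defaults reproduce the reference study conditions: 44 subjects with
curve-type prevalence 9/12/6/17 over (3c, 3cp, 4c, 4cp) and a panel of
10 raters in three tiers — 2 experienced (a=0.90, c=0.20), 6
well-trained (a=0.75, c=0.15) and 2 others (a=0.60, c=0.10) — with a 1%
missing rate.  Consistency is deliberately low: raters were blinded to
their first-round labels and saw the subjects in a new random order, so
the second occasion is mostly a fresh judgement with modest carry-over.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .agreement import RatingMatrix, WeightMatrix, schroth_weights
from .classifier import CATEGORIES

__all__ = [
    "RaterProfile",
    "StudyConfig",
    "default_config",
    "build_confusion",
    "simulate_study",
    "expected_intra_pa",
]

#: Floor added to zero weight entries so every confusion has support.
CONFUSION_FLOOR = 0.05

#: Reference-study prevalence over (3c, 3cp, 4c, 4cp): 9/12/6/17 of 44.
DEFAULT_PREVALENCE = (9 / 44, 12 / 44, 6 / 44, 17 / 44)


@dataclass(frozen=True)
class RaterProfile:
    rater_id: str
    accuracy: float
    consistency: float
    missing_rate: float = 0.0
    group: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.accuracy <= 1:
            raise ValueError("accuracy must lie in (0, 1]")
        if not 0 <= self.consistency <= 1:
            raise ValueError("consistency must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class StudyConfig:
    n_subjects: int = 44
    prevalence: tuple[float, ...] = DEFAULT_PREVALENCE
    raters: tuple[RaterProfile, ...] = ()
    weights: WeightMatrix = field(default_factory=schroth_weights)
    seed: int = 0
    categories: tuple[str, ...] = CATEGORIES

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.raters) < 2:
            raise ValueError("need at least 2 raters")
        p = np.asarray(self.prevalence, dtype=float)
        if len(p) != len(self.categories):
            raise ValueError("prevalence length must match category count")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("prevalence must sum to 1")


def default_raters() -> tuple[RaterProfile, ...]:
    """The three-tier 10-rater panel used as the study default."""
    profiles = []
    for i in range(2):
        profiles.append(
            RaterProfile(f"experienced_{i + 1}", 0.90, 0.20, 0.01, "experienced")
        )
    for i in range(6):
        profiles.append(
            RaterProfile(f"trained_{i + 1}", 0.75, 0.15, 0.01, "well-trained")
        )
    for i in range(2):
        profiles.append(RaterProfile(f"other_{i + 1}", 0.60, 0.10, 0.01, ""))
    return tuple(profiles)


def default_config(seed: int = 0) -> StudyConfig:
    return StudyConfig(raters=default_raters(), seed=seed)


def default_groups(
    raters: Sequence[RaterProfile] | None = None,
) -> dict[str, list[str]]:
    """Rater -> subgroup memberships for the default panel.

    Subgroups are nested as in the reference design: the experienced
    raters also count as well-trained (they report full understanding of
    the algorithm), so ``well-trained`` contains them plus the trained
    tier, and ``all`` adds the remaining raters.  This nesting is what
    produces the characteristic ordering experienced > well-trained >
    all in the subgroup analysis.
    """
    if raters is None:
        raters = default_raters()
    mapping: dict[str, list[str]] = {}
    for p in raters:
        if not p.group:
            continue
        mapping[p.rater_id] = [p.group]
        if p.group == "experienced":
            mapping[p.rater_id].append("well-trained")
    return mapping


def build_confusion(
    profile: RaterProfile, weights: WeightMatrix
) -> np.ndarray:
    """Row-stochastic confusion matrix C[truth, assigned] for one rater."""
    q = weights.q
    w = weights.values.copy()
    w[w == 0] = CONFUSION_FLOOR
    a = profile.accuracy
    C = np.empty((q, q))
    for t in range(q):
        off = w[t].copy()
        off[t] = 0.0
        total = off.sum()
        C[t] = (1 - a) * off / total
        C[t, t] = a
    return C


def expected_intra_pa(
    profile: RaterProfile,
    prevalence: Sequence[float] = DEFAULT_PREVALENCE,
    weights: WeightMatrix | None = None,
) -> float:
    """Closed-form expected test-retest raw agreement for one rater.

    Conditions on both ratings being observed, so the missing rate does
    not enter.
    """
    if weights is None:
        weights = schroth_weights()
    C = build_confusion(profile, weights)
    pi = np.asarray(prevalence, dtype=float)
    repeat = profile.consistency + (1 - profile.consistency) * (C**2).sum(axis=1)
    return float(pi @ repeat)


def simulate_study(
    config: StudyConfig,
) -> tuple[pd.Series, RatingMatrix, RatingMatrix]:
    """Simulate one two-occasion study.

    Returns ``(truth, occasion-1 matrix, occasion-2 matrix)``; fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cats = np.array(config.categories, dtype=object)
    q = len(cats)
    subjects = [f"s{i + 1:03d}" for i in range(config.n_subjects)]
    truth_idx = rng.choice(q, size=config.n_subjects, p=config.prevalence)
    truth = pd.Series(cats[truth_idx], index=subjects, name="truth")

    occ1 = pd.DataFrame(index=subjects, dtype=object)
    occ2 = pd.DataFrame(index=subjects, dtype=object)
    for profile in config.raters:
        C = build_confusion(profile, config.weights)
        # occasion 1: fresh draw from the confusion row of the truth
        u = rng.random((config.n_subjects, 1))
        first = (u > C[truth_idx].cumsum(axis=1)).sum(axis=1)
        # occasion 2: copy with prob c, else fresh draw
        copy = rng.random(config.n_subjects) < profile.consistency
        u2 = rng.random((config.n_subjects, 1))
        fresh = (u2 > C[truth_idx].cumsum(axis=1)).sum(axis=1)
        second = np.where(copy, first, fresh)
        col1 = cats[first].astype(object)
        col2 = cats[second].astype(object)
        if profile.missing_rate > 0:
            col1[rng.random(config.n_subjects) < profile.missing_rate] = np.nan
            col2[rng.random(config.n_subjects) < profile.missing_rate] = np.nan
        occ1[profile.rater_id] = col1
        occ2[profile.rater_id] = col2

    return (
        truth,
        RatingMatrix(occ1, config.categories, occasion=1),
        RatingMatrix(occ2, config.categories, occasion=2),
    )
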