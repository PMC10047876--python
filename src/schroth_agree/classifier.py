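"""Rule engine for Schroth curve-type classification.

The Schroth approach to scoliosis-specific exercise distinguishes four
clinical curve patterns — two thoracic (``3c``, ``3cp``) and two
thoracolumbar/lumbar (``4c``, ``4cp``); the ``p`` suffix marks an
imbalanced (displaced) pelvis.  Therapists reach the label through a
fixed sequence of yes/no postural judgements:

1. Is the pelvis displaced relative to the midline (unbalanced)?
   If yes:

   2. Do the lumbar block and the pelvis block deviate in the same
      direction ("coupled")?  Coupled -> **3cp**, uncoupled -> **4cp**.

   If no (pelvis balanced), the coupling and hip-prominence checks are
   recorded as confirmatory observations, and:

   3. Is the thoracic prominence (rib hump) judged more significant
      than the lumbar prominence?  Yes -> **3c**, otherwise -> **4c**.

The engine is a total, deterministic function of four booleans and
returns a full decision trace so that each branch judgement can be
audited (or scored for reliability at the branch level).

Ties between thoracic and lumbar prominence belong to the "otherwise"
branch: callers must encode a tie as ``thoracic_dominant=False``, which
yields 4c.  Curve laterality (left/right convexity) is not part of the
label; the engine classifies the pattern only.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

__all__ = [
    "CurveType",
    "PosturalObservation",
    "DecisionTrace",
    "classify",
    "truth_table",
    "classify_table",
    "classify_csv",
]


class CurveType(str, enum.Enum):
    """The four Schroth curve patterns."""

    THORACIC_BALANCED = "3c"
    THORACIC_PELVIS = "3cp"
    LUMBAR_BALANCED = "4c"
    LUMBAR_PELVIS = "4cp"

    def __str__(self) -> str:  # lossless round-trip via str()
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "CurveType":
        try:
            return cls(label)
        except ValueError:
            raise ValueError(
                f"unknown curve type {label!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: Category labels in canonical order, shared by the agreement machinery.
CATEGORIES: tuple[str, ...] = tuple(m.value for m in CurveType)


@dataclass(frozen=True)
class PosturalObservation:
    """One subject's branch-level postural judgements.

    All four fields are always present; fields irrelevant to the branch
    actually taken are recorded in the trace but do not affect the label.

    Parameters
    ----------
    pelvis_balanced
        Pelvis not displaced relative to the midline.
    pelvis_lumbar_coupled
        Lumbar block and pelvis block deviate in the same direction.
    prominent_hip
        A prominent hip is observed.
    thoracic_dominant
        Thoracic prominence judged more significant than the lumbar
        prominence.  Encode a tie as ``False``.
    """

    pelvis_balanced: bool
    pelvis_lumbar_coupled: bool
    prominent_hip: bool
    thoracic_dominant: bool


@dataclass(frozen=True)
class DecisionTrace:
    """Ordered record of every branch judgement and the final label."""

    steps: tuple[tuple[str, bool], ...]
    curve_type: CurveType

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("decision trace cannot be empty")

    def serialize(self) -> str:
        """Compact ``step=yes/no;...`` form for CSV output."""
        return ";".join(
            f"{name}={'yes' if ans else 'no'}" for name, ans in self.steps
        )


def classify(obs: PosturalObservation) -> tuple[CurveType, DecisionTrace]:
    """Classify one postural observation.

    Total over all 16 boolean combinations.  Returns the curve type and
    the replayable decision trace.
    """
    steps: list[tuple[str, bool]] = []
    steps.append(("pelvis_balanced", obs.pelvis_balanced))
    if not obs.pelvis_balanced:
        steps.append(("pelvis_lumbar_coupled", obs.pelvis_lumbar_coupled))
        label = (
            CurveType.THORACIC_PELVIS
            if obs.pelvis_lumbar_coupled
            else CurveType.LUMBAR_PELVIS
        )
    else:
        # Confirmatory observations on the balanced branch; the
        # prominence comparison alone decides 3c vs 4c.
        steps.append(("pelvis_lumbar_coupled", obs.pelvis_lumbar_coupled))
        steps.append(("prominent_hip", obs.prominent_hip))
        steps.append(("thoracic_dominant", obs.thoracic_dominant))
        label = (
            CurveType.THORACIC_BALANCED
            if obs.thoracic_dominant
            else CurveType.LUMBAR_BALANCED
        )
    return label, DecisionTrace(tuple(steps), label)


def truth_table() -> list[tuple[PosturalObservation, CurveType]]:
    """Enumerate all 16 observations with their classification."""
    rows = []
    for bits in itertools.product([False, True], repeat=4):
        obs = PosturalObservation(*bits)
        rows.append((obs, classify(obs)[0]))
    return rows


_BOOL_COLS = (
    "pelvis_balanced",
    "pelvis_lumbar_coupled",
    "prominent_hip",
    "thoracic_dominant",
)

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _parse_bool(value: object, column: str, row: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ValueError(
        f"row {row}: column {column!r} has non-boolean value {value!r}"
    )


def classify_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Batch-classify a table of observations.

    Expects columns ``subject_id`` plus the four boolean feature columns;
    returns a copy with ``curve_type`` and ``trace`` appended.
    """
    missing = [c for c in ("subject_id", *_BOOL_COLS) if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    out = frame.copy()
    labels, traces = [], []
    for idx, row in frame.iterrows():
        obs = PosturalObservation(
            *(_parse_bool(row[c], c, int(idx)) for c in _BOOL_COLS)
        )
        label, trace = classify(obs)
        labels.append(label.value)
        traces.append(trace.serialize())
    out["curve_type"] = labels
    out["trace"] = traces
    return out


def classify_csv(input_path: str | Path, output_path: str | Path) -> pd.DataFrame:
    """Read an observation CSV, classify, and write the result CSV."""
    result = classify_table(pd.read_csv(input_path))
    result.to_csv(output_path, index=False)
    return result


def iter_curve_types() -> Iterator[CurveType]:
    return iter(CurveType)
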