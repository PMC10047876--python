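"""Fisher-transform pooling, benchmark banding and precision criteria.

Agreement coefficients live in (-1, 1], so averaging them directly
biases the mean toward zero.  Pooling instead maps each coefficient
through Fisher's z transform (atanh), averages on the unbounded scale,
and back-transforms (tanh) — the same device used to average
correlation coefficients.

Benchmarking follows the conservative convention of interpreting only
the "significant part" of an estimate: a sample-size-dependent critical
value (0.08 for 44 subjects, 10 raters, 4 categories) is subtracted
before the estimate is placed on the Landis–Koch-style scale.  Clinical
adequacy is a separate a-priori threshold on the raw estimate
(default >= 0.61).

The precision criteria mirror the sample-size planning rules for
agreement studies: the coefficient of variation of percent agreement
(se / pa) must not exceed 15%, and the relative error (95% CI
half-width / pa) must not exceed 20%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .agreement import AgreementResult, Z_95

__all__ = [
    "BenchmarkScale",
    "PooledResult",
    "PrecisionReport",
    "fisher_pool",
    "benchmark",
    "precision_metrics",
    "LANDIS_KOCH_BANDS",
]

#: (lower bound, label) bands partitioning (-1, 1].  A value belongs to
#: the band with the largest lower bound not exceeding it.
LANDIS_KOCH_BANDS: tuple[tuple[float, str], ...] = (
    (-1.0, "poor"),
    (0.0, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


@dataclass(frozen=True)
class BenchmarkScale:
    """Interpretation scale: bands + critical value + adequacy threshold."""

    bands: tuple[tuple[float, str], ...] = LANDIS_KOCH_BANDS
    critical_value: float = 0.08
    adequacy_threshold: float = 0.61

    def __post_init__(self) -> None:
        lowers = [b[0] for b in self.bands]
        if lowers != sorted(lowers):
            raise ValueError("band lower bounds must be increasing")
        if self.critical_value < 0:
            raise ValueError("critical value must be >= 0")
        if not 0 < self.adequacy_threshold < 1:
            raise ValueError("adequacy threshold must lie in (0, 1)")

    def band_of(self, value: float) -> str:
        label = self.bands[0][1]
        for lower, name in self.bands:
            if value >= lower:
                label = name
        return label


@dataclass(frozen=True)
class PooledResult:
    """Fisher-pooled mean of several coefficients."""

    estimate: float
    transforms: tuple[float, ...]
    se_z: float
    ci_low: float
    ci_high: float

    @property
    def n(self) -> int:
        return len(self.transforms)


def fisher_pool(coefficients: Sequence[float]) -> PooledResult:
    """Pool coefficients via atanh -> mean -> tanh.

    The 95% CI comes from the standard error of the mean on the z scale,
    back-transformed.  A single input is returned unchanged with a
    zero-width interval.  Inputs of exactly +/-1 are rejected (infinite
    transform).
    """
    values = np.asarray(list(coefficients), dtype=float)
    if values.size == 0:
        raise ValueError("cannot pool an empty list of coefficients")
    if np.any(np.abs(values) >= 1):
        raise ValueError(
            "coefficients must lie strictly inside (-1, 1); "
            "values of exactly +/-1 have an infinite Fisher transform"
        )
    z = np.arctanh(values)
    mean_z = float(z.mean())
    if values.size == 1:
        se_z = 0.0
    else:
        se_z = float(z.std(ddof=1) / math.sqrt(z.size))
    return PooledResult(
        estimate=float(np.tanh(mean_z)),
        transforms=tuple(float(v) for v in z),
        se_z=se_z,
        ci_low=float(np.tanh(mean_z - Z_95 * se_z)),
        ci_high=float(np.tanh(mean_z + Z_95 * se_z)),
    )


def benchmark(
    estimate: float, scale: BenchmarkScale | None = None
) -> tuple[float, str, bool]:
    """Band an estimate after subtracting the critical value.

    Returns ``(significant_part, band_label, adequate)`` where
    ``significant_part = estimate - critical_value``, the band is looked
    up on the significant part, and adequacy compares the *raw* estimate
    with the a-priori threshold.
    """
    if scale is None:
        scale = BenchmarkScale()
    if not -1 < estimate <= 1:
        raise ValueError("estimate must lie in (-1, 1]")
    significant = estimate - scale.critical_value
    return (
        significant,
        scale.band_of(significant),
        estimate >= scale.adequacy_threshold,
    )


@dataclass(frozen=True)
class PrecisionReport:
    """Precision criteria for a percent-agreement result."""

    cv: float
    relative_error: float
    relative_error_full_width: float
    cv_ok: bool
    rel_ok: bool


def precision_metrics(
    result: AgreementResult,
    cv_limit: float = 0.15,
    rel_limit: float = 0.20,
) -> PrecisionReport:
    """Coefficient of variation and relative error of percent agreement.

    ``cv = se / pa``; ``relative_error`` uses the 95% CI half-width over
    pa (the flagged metric); the full-width variant is also reported for
    transparency.  Both comparisons are boundary-inclusive.
    """
    pa = result.pa
    if not pa > 0:
        raise ValueError("percent agreement must be > 0 for precision metrics")
    cv = result.se / pa
    half_width = (result.ci_high - result.ci_low) / 2
    rel = half_width / pa
    return PrecisionReport(
        cv=cv,
        relative_error=rel,
        relative_error_full_width=2 * rel,
        cv_ok=cv <= cv_limit,
        rel_ok=rel <= rel_limit,
    )
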