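"""Readers, writers, validation and study-report generation.

File formats
------------
Ratings CSV (long format)
    Columns ``subject_id, rater_id, occasion, rating``; occasion is 1
    or 2; rating is a declared category label or empty for missing.
Weights CSV
    q x q matrix with category labels as header row and first column.
Groups CSV
    Columns ``rater_id, group``; a rater may appear in several groups
    (e.g. the experienced raters are typically also well-trained).

The study report mirrors the conventional layout of a reliability
study's results tables: one intra-rater row per rater (unweighted and weighted
coefficient and percent agreement, each with 95% CI), Fisher-pooled
group rows, and inter-rater rows per occasion plus their pooled
headline value.  Coefficients are rounded to 2 decimals and percents to
1 decimal in the text rendering; the CSV keeps full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement import (
    AgreementResult,
    RatingMatrix,
    WeightMatrix,
    gwet_ac,
    identity_weights,
    intra_rater,
    percent_agreement,
    schroth_weights,
)
from .classifier import CATEGORIES
from .pooling import BenchmarkScale, benchmark, fisher_pool, precision_metrics

__all__ = [
    "RatingsValidationError",
    "StudyReport",
    "read_ratings",
    "write_ratings",
    "validate_ratings",
    "read_weights",
    "write_weights",
    "read_groups",
    "run_pipeline",
]

logger = logging.getLogger("schroth_agree")

_RATING_COLUMNS = ("subject_id", "rater_id", "occasion", "rating")


class RatingsValidationError(ValueError):
    """Carries the complete list of violations found in a ratings file."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__(
            "invalid ratings file:\n" + "\n".join(f"  - {e}" for e in self.errors)
        )


def validate_ratings(
    path: str | Path, categories: Sequence[str] = CATEGORIES
) -> dict[int, RatingMatrix]:
    """Read and validate a long-format ratings CSV.

    Returns one RatingMatrix per occasion, or raises
    :class:`RatingsValidationError` listing every violation with its
    line number (header = line 1).
    """
    table = pd.read_csv(path, dtype=str, keep_default_na=False)
    errors: list[str] = []
    missing_cols = [c for c in _RATING_COLUMNS if c not in table.columns]
    if missing_cols:
        raise RatingsValidationError(
            [f"missing required columns: {missing_cols}"]
        )
    allowed = set(categories)
    seen: set[tuple[str, str, str]] = set()
    for pos, row in enumerate(table.itertuples(index=False)):
        line = pos + 2  # header is line 1
        if row.occasion not in ("1", "2"):
            errors.append(
                f"line {line}: occasion {row.occasion!r} must be 1 or 2"
            )
        rating = row.rating.strip()
        if rating and rating not in allowed:
            errors.append(
                f"line {line}: rating {rating!r} not in allowed set "
                f"{sorted(allowed)}"
            )
        key = (row.subject_id, row.rater_id, row.occasion)
        if key in seen:
            errors.append(
                f"line {line}: duplicate rating for subject "
                f"{row.subject_id!r}, rater {row.rater_id!r}, "
                f"occasion {row.occasion}"
            )
        seen.add(key)
    if errors:
        raise RatingsValidationError(errors)
    table["rating"] = table["rating"].str.strip().replace("", np.nan)
    out: dict[int, RatingMatrix] = {}
    for occ in (1, 2):
        sub = table[table["occasion"] == str(occ)]
        if not len(sub):
            continue
        out[occ] = RatingMatrix.from_long(sub, categories, occasion=occ)
    return out


def read_ratings(
    path: str | Path, categories: Sequence[str] = CATEGORIES
) -> dict[int, RatingMatrix]:
    """Alias of :func:`validate_ratings` (reading always validates)."""
    return validate_ratings(path, categories)


def write_ratings(
    matrices: Mapping[int, RatingMatrix], path: str | Path
) -> None:
    """Write occasion matrices back to the long CSV format."""
    rows = []
    for occ in sorted(matrices):
        frame = matrices[occ].frame
        for subject in frame.index:
            for rater in frame.columns:
                value = frame.at[subject, rater]
                rows.append(
                    {
                        "subject_id": subject,
                        "rater_id": rater,
                        "occasion": occ,
                        "rating": "" if pd.isna(value) else value,
                    }
                )
    pd.DataFrame(rows, columns=list(_RATING_COLUMNS)).to_csv(path, index=False)


def read_weights(path: str | Path) -> WeightMatrix:
    frame = pd.read_csv(path, index_col=0)
    cats = tuple(str(c) for c in frame.columns)
    if tuple(str(i) for i in frame.index) != cats:
        raise ValueError("weights CSV row labels must match column labels")
    return WeightMatrix(frame.to_numpy(dtype=float), cats)


def write_weights(weights: WeightMatrix, path: str | Path) -> None:
    weights.to_frame().to_csv(path)


def read_groups(path: str | Path) -> dict[str, list[str]]:
    """Read the rater->groups mapping; a rater may be in several groups."""
    table = pd.read_csv(path, dtype=str)
    for col in ("rater_id", "group"):
        if col not in table.columns:
            raise ValueError(f"groups CSV missing column {col!r}")
    mapping: dict[str, list[str]] = {}
    for row in table.itertuples(index=False):
        mapping.setdefault(row.rater_id, []).append(row.group)
    return mapping


@dataclass
class StudyReport:
    """Full reliability report: intra-rater, group and inter-rater rows."""

    intra: pd.DataFrame
    groups: pd.DataFrame
    inter: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        combined = pd.concat(
            [
                self.intra.assign(section="intra"),
                self.groups.assign(section="group"),
                self.inter.assign(section="inter"),
            ],
            ignore_index=True,
        )
        combined.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyReport":
        combined = pd.read_csv(path)
        parts = {}
        for name in ("intra", "group", "inter"):
            part = combined[combined["section"] == name].drop(columns="section")
            parts[name] = part.reset_index(drop=True)
        return cls(intra=parts["intra"], groups=parts["group"], inter=parts["inter"])

    def to_text(self) -> str:
        """Plain-text tables in the conventional column order."""

        def fmt_coef(est, lo, hi):
            return f"{est:.2f} ({lo:.2f}-{hi:.2f})"

        def fmt_pct(est, lo, hi):
            return f"{100 * est:.1f} ({100 * lo:.1f}-{100 * hi:.1f})"

        lines = [
            "Intra-rater reliability",
            f"{'Rater':<18}{'AC1 (95% CI)':<22}{'% Agr (95% CI)':<24}"
            f"{'wAC1 (95% CI)':<22}{'w% Agr (95% CI)':<24}",
        ]
        for _, r in self.intra.iterrows():
            lines.append(
                f"{r['label']:<18}"
                f"{fmt_coef(r['ac1'], r['ac1_lo'], r['ac1_hi']):<22}"
                f"{fmt_pct(r['pa'], r['pa_lo'], r['pa_hi']):<24}"
                f"{fmt_coef(r['wac1'], r['wac1_lo'], r['wac1_hi']):<22}"
                f"{fmt_pct(r['wpa'], r['wpa_lo'], r['wpa_hi']):<24}"
            )
        lines.append("")
        lines.append("Group means (Fisher-pooled)")
        for _, r in self.groups.iterrows():
            lines.append(
                f"{r['label']:<18}"
                f"{fmt_coef(r['ac1'], r['ac1_lo'], r['ac1_hi']):<22}"
                f"{fmt_pct(r['pa'], r['pa_lo'], r['pa_hi']):<24}"
                f"{fmt_coef(r['wac1'], r['wac1_lo'], r['wac1_hi']):<22}"
                f"{fmt_pct(r['wpa'], r['wpa_lo'], r['wpa_hi']):<24}"
            )
        lines.append("")
        lines.append("Inter-rater reliability")
        for _, r in self.inter.iterrows():
            lines.append(
                f"{r['label']:<18}"
                f"{fmt_coef(r['ac1'], r['ac1_lo'], r['ac1_hi']):<22}"
                f"{fmt_coef(r['wac1'], r['wac1_lo'], r['wac1_hi']):<22}"
                f"band={r['band']:<16}adequate={bool(r['adequate'])}"
            )
        return "\n".join(lines)


def _pool(values: Sequence[float]):
    """Fisher-pool report rows, tolerating boundary estimates.

    Perfect simulated studies produce coefficients of exactly 1, whose
    Fisher transform is infinite; values are nudged just inside the open
    interval so the pooled mean of identical boundary values round-trips
    to that value at report precision.
    """
    eps = 1e-12
    clipped = np.clip(np.asarray(values, dtype=float), -1 + eps, 1 - eps)
    return fisher_pool(clipped)


def _result_cols(prefix: str, res: AgreementResult) -> dict[str, float]:
    return {
        prefix: res.estimate,
        f"{prefix}_lo": res.ci_low,
        f"{prefix}_hi": res.ci_high,
        f"{prefix}_se": res.se,
    }


def run_pipeline(
    ratings_t1: RatingMatrix,
    ratings_t2: RatingMatrix,
    weights: WeightMatrix | None = None,
    rater_groups: Mapping[str, Sequence[str]] | None = None,
    scale: BenchmarkScale | None = None,
) -> StudyReport:
    """Compute the full reliability report for a two-occasion study.

    Per rater: unweighted and weighted test-retest coefficients and
    percent agreements.  Per group (``all`` plus every named group):
    Fisher-pooled means of the member rows.  Inter-rater: per-occasion
    multi-rater coefficients plus their Fisher-pooled headline value.
    Benchmark bands use the significant-part rule; precision flags apply
    to the unweighted percent agreement.
    """
    if weights is None:
        weights = schroth_weights()
    if scale is None:
        scale = BenchmarkScale()
    if rater_groups is None:
        rater_groups = {}
    raters = list(ratings_t1.frame.columns)
    unknown = set(rater_groups) - set(raters)
    if unknown:
        raise ValueError(f"group file names unknown rater ids: {sorted(unknown)}")
    ident = identity_weights(ratings_t1.categories)

    intra_rows = []
    for rater in raters:
        ac1 = intra_rater(ratings_t1, ratings_t2, rater, ident)
        wac1 = intra_rater(ratings_t1, ratings_t2, rater, weights)
        pair = pd.DataFrame(
            {
                "occasion_1": ratings_t1.frame[rater],
                "occasion_2": ratings_t2.frame[rater],
            }
        )
        pair_matrix = RatingMatrix(pair, ratings_t1.categories)
        pa = percent_agreement(pair_matrix, ident)
        wpa = percent_agreement(pair_matrix, weights)
        logger.info(
            "intra-rater %s: %d subjects used (of %d)",
            rater,
            ac1.n_subjects_used,
            ratings_t1.n_subjects,
        )
        significant, band, adequate = benchmark(ac1.estimate, scale)
        precision = precision_metrics(pa)
        intra_rows.append(
            {
                "label": str(rater),
                **_result_cols("ac1", ac1),
                **_result_cols("pa", pa),
                **_result_cols("wac1", wac1),
                **_result_cols("wpa", wpa),
                "n_subjects": ac1.n_subjects_used,
                "significant_part": significant,
                "band": band,
                "adequate": adequate,
                "cv": precision.cv,
                "cv_ok": precision.cv_ok,
                "relative_error": precision.relative_error,
                "rel_ok": precision.rel_ok,
            }
        )
    intra = pd.DataFrame(intra_rows)

    group_members = {"all": raters}
    for rater, names in rater_groups.items():
        for name in names:
            group_members.setdefault(name, []).append(rater)

    group_rows = []
    for name, members in group_members.items():
        rows = intra[intra["label"].isin([str(m) for m in members])]
        entry: dict[str, object] = {"label": name, "n_raters": len(rows)}
        for col in ("ac1", "pa", "wac1", "wpa"):
            pooled = _pool(rows[col].tolist())
            entry[col] = pooled.estimate
            entry[f"{col}_lo"] = pooled.ci_low
            entry[f"{col}_hi"] = pooled.ci_high
        significant, band, adequate = benchmark(float(entry["ac1"]), scale)
        entry.update(
            significant_part=significant, band=band, adequate=adequate
        )
        group_rows.append(entry)
    groups = pd.DataFrame(group_rows)

    inter_rows = []
    per_occ: dict[str, list[float]] = {"ac1": [], "wac1": []}
    for matrix in (ratings_t1, ratings_t2):
        occ = matrix.occasion
        ac1 = gwet_ac(matrix, ident, label=f"occasion {occ}")
        wac1 = gwet_ac(matrix, weights, label=f"occasion {occ}")
        logger.info(
            "inter-rater occasion %s: %d subjects used",
            occ,
            ac1.n_subjects_used,
        )
        significant, band, adequate = benchmark(ac1.estimate, scale)
        inter_rows.append(
            {
                "label": f"occasion {occ}",
                **_result_cols("ac1", ac1),
                **_result_cols("wac1", wac1),
                "n_subjects": ac1.n_subjects_used,
                "significant_part": significant,
                "band": band,
                "adequate": adequate,
            }
        )
        per_occ["ac1"].append(ac1.estimate)
        per_occ["wac1"].append(wac1.estimate)
    pooled_entry: dict[str, object] = {"label": "pooled"}
    for col in ("ac1", "wac1"):
        pooled = _pool(per_occ[col])
        pooled_entry[col] = pooled.estimate
        pooled_entry[f"{col}_lo"] = pooled.ci_low
        pooled_entry[f"{col}_hi"] = pooled.ci_high
    significant, band, adequate = benchmark(float(pooled_entry["ac1"]), scale)
    pooled_entry.update(
        significant_part=significant, band=band, adequate=adequate
    )
    inter_rows.append(pooled_entry)
    inter = pd.DataFrame(inter_rows)

    return StudyReport(intra=intra, groups=groups, inter=inter)
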