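"""Quality categories, the 1-6 editing scorecard, and summary aggregation.

Each metric value is sorted into one of three clinical categories —
``best`` (clinically usable as-is), ``good`` (minor adjustments), and
``suboptimal`` (needs modification) — using threshold tables; a 1-6
ordinal scorecard grades the editing burden of a contour from the number
of edited slices and the kind of edit. Aggregation turns per-case
per-organ metric results into per-organ means, per-model overall means
(unweighted across organs), and radar-plot-ready normalized values.

A bundled benchmark table (``load_benchmark_table``) carries published
per-organ mean accuracies of three abdominal-MRI auto-segmentation models
(a T1-only model, a T2-only model, and a multi-sequence model over twelve
organs-at-risk); it serves as a worked example and regression fixture for
the aggregation arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "GradeTables",
    "EditRecord",
    "EDIT_KINDS",
    "METRIC_DIRECTIONS",
    "grade_metric",
    "score_edits",
    "contour_category",
    "aggregate",
    "percent_best_good",
    "load_benchmark_table",
]

#: Comparison direction per metric: "ge" = higher is better (threshold is a
#: floor), "le" = lower is better, "abs_le" = graded on the magnitude.
METRIC_DIRECTIONS = {
    "dsc": "ge",
    "mda_mm": "le",
    "hd95_mm": "le",
    "pvd_pct": "abs_le",
    "sdsc": "ge",
    "rapl_mm_per_cc": "le",
}

_DEFAULT_BEST = {
    "dsc": 0.9, "mda_mm": 1.5, "hd95_mm": 5.0,
    "pvd_pct": 3.0, "sdsc": 0.85, "rapl_mm_per_cc": 5.0,
}
_DEFAULT_GOOD = {
    "dsc": 0.8, "mda_mm": 3.0, "hd95_mm": 10.0,
    "pvd_pct": 6.0, "sdsc": 0.75, "rapl_mm_per_cc": 10.0,
}

EDIT_KINDS = (
    "none",
    "delete_or_expand",
    "fix_incomplete",
    "junction_or_hilum",
    "majority_redraw",
    "full_redo",
)


@dataclass
class GradeTables:
    """Per-metric category thresholds; boundary values are inclusive."""

    best: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BEST))
    good: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_GOOD))

    def __post_init__(self) -> None:
        for metric, direction in METRIC_DIRECTIONS.items():
            if metric not in self.best or metric not in self.good:
                raise ValueError(f"threshold tables must cover {metric!r}")
            b, g = self.best[metric], self.good[metric]
            ok = b >= g if direction == "ge" else b <= g
            if not ok:
                raise ValueError(
                    f"'best' threshold for {metric} ({b}) is looser than 'good' ({g})")


def grade_metric(metric_name: str, value: float,
                 tables: GradeTables | None = None) -> str:
    """Categorize one metric value as best / good / suboptimal."""
    tables = tables or GradeTables()
    if metric_name not in METRIC_DIRECTIONS:
        raise KeyError(f"unknown metric {metric_name!r}; "
                       f"expected one of {sorted(METRIC_DIRECTIONS)}")
    if value is None or not np.isfinite(value):
        raise ValueError(f"cannot grade non-finite value {value!r} for {metric_name}")
    direction = METRIC_DIRECTIONS[metric_name]
    v = abs(value) if direction == "abs_le" else float(value)

    def passes(threshold: float) -> bool:
        return v >= threshold if direction == "ge" else v <= threshold

    if passes(tables.best[metric_name]):
        return "best"
    if passes(tables.good[metric_name]):
        return "good"
    return "suboptimal"


@dataclass
class EditRecord:
    """Editing burden observed (or anticipated) for one organ contour."""

    organ: str
    n_edited_slices: int
    total_slices: int
    edit_kind: str = "none"

    def __post_init__(self) -> None:
        if self.edit_kind not in EDIT_KINDS:
            raise ValueError(f"unknown edit_kind {self.edit_kind!r}")
        if not (0 <= self.n_edited_slices <= self.total_slices):
            raise ValueError(
                f"n_edited_slices={self.n_edited_slices} outside "
                f"[0, total_slices={self.total_slices}]")

    @property
    def fraction_edited(self) -> float:
        return self.n_edited_slices / self.total_slices if self.total_slices else 0.0


def score_edits(record: EditRecord) -> int:
    """The 1-6 editing scorecard.

    1 no edits; 2 few slices (< 5) with deletions/expansions; 3 fewer than
    10 slices fixing incomplete segmentation; 4 edits at organ junctions or
    hilum, or around 20 slices while still under half the organ; 5 more
    than half the slices; 6 more than 80% of slices or a full redo. Rules
    are checked from worst to best so ties resolve toward the higher
    (worse) score; records matching no specific rule fall back on the
    slice count alone.
    """
    n, frac, kind = record.n_edited_slices, record.fraction_edited, record.edit_kind
    if kind == "full_redo" or frac > 0.8:
        return 6
    if frac > 0.5 or kind == "majority_redraw":
        return 5
    if n == 0:
        return 1
    if kind == "junction_or_hilum" or n >= 20:
        return 4
    if kind == "fix_incomplete" and n < 10:
        return 3
    if kind == "delete_or_expand" and n < 5:
        return 2
    # fallback by extent only
    if n < 5:
        return 2
    if n < 10:
        return 3
    return 4


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

_METRICS = list(METRIC_DIRECTIONS)


def aggregate(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summarize per-case per-organ metric results.

    ``results`` needs ``model`` and ``organ`` columns plus any subset of
    the six metric columns (``case_id`` optional; a table of per-organ
    means is accepted as-is). Returns:

    - ``per_organ``: mean of each metric per (organ, model) across cases;
    - ``overall``: per-model unweighted mean of the per-organ means — each
      organ counts once regardless of how many cases or voxels it has;
    - ``radar``: per-organ means divided by the maximum magnitude of that
      metric across all organs and models, so the largest cell maps to 1.
    """
    if results.empty:
        raise ValueError("cannot aggregate an empty result collection")
    for col in ("model", "organ"):
        if col not in results.columns:
            raise ValueError(f"results must have a {col!r} column")
    metrics = [m for m in _METRICS if m in results.columns]
    if not metrics:
        raise ValueError("results contain none of the six metric columns")

    per_organ = (results.groupby(["organ", "model"], sort=False)[metrics]
                 .mean().reset_index())
    overall = (per_organ.groupby("model", sort=False)[metrics]
               .mean().reset_index())

    radar = per_organ.copy()
    for m in metrics:
        max_mag = per_organ[m].abs().max()
        radar[m] = per_organ[m].abs() / max_mag if max_mag > 0 else 0.0
    return {"per_organ": per_organ, "overall": overall, "radar": radar}


def contour_category(row, tables: GradeTables | None = None) -> str:
    """Single category for one contour: majority vote over its six metric
    categories, ties resolved toward the worse category."""
    tables = tables or GradeTables()
    order = ("suboptimal", "good", "best")  # worst first for tie-breaks
    votes = {c: 0 for c in order}
    n_graded = 0
    for metric in _METRIC_VOTE_ORDER:
        value = row.get(metric) if hasattr(row, "get") else getattr(row, metric, None)
        if value is None or (isinstance(value, float) and not np.isfinite(value)):
            continue
        votes[grade_metric(metric, value, tables)] += 1
        n_graded += 1
    if n_graded == 0:
        raise ValueError("no gradable metric values in row")
    return max(order, key=lambda c: (votes[c], -order.index(c)))


_METRIC_VOTE_ORDER = _METRICS


def percent_best_good(results: pd.DataFrame,
                      tables: GradeTables | None = None) -> float:
    """Percent of contours whose combined category is best or good."""
    tables = tables or GradeTables()
    if results.empty:
        raise ValueError("cannot categorize an empty result collection")
    cats = results.apply(lambda row: contour_category(row, tables), axis=1)
    return 100.0 * float((cats != "suboptimal").mean())


def load_benchmark_table() -> pd.DataFrame:
    """Published per-organ mean accuracies of the three benchmark models."""
    with resources.files("contourqa.data").joinpath(
            "benchmark_organ_means.csv").open() as fh:
        return pd.read_csv(fh)
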