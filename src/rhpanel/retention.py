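"""Retention-frequency estimation, hybrid selection and method comparison.

A marker's retention frequency f is the fraction of *informative* hybrids
(unknown calls excluded from the denominator) in which it is present.  Class
and genome-wide summaries are unweighted means of per-marker f values.
Genotyping methods are compared marker-by-marker with paired two-sided
t-tests, reported raw alongside a Bonferroni column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ABSENT, PRESENT, UNKNOWN, GenotypeMatrix, MarkerRecord, ValidationError


class UndefinedRetentionError(ValueError):
    """A marker has no informative calls, so f is undefined."""


@dataclass(frozen=True)
class MarkerRetention:
    marker_id: str
    f: float
    n_pos: int
    n_neg: int
    n_unknown: int

    @property
    def n_informative(self) -> int:
        return self.n_pos + self.n_neg


@dataclass
class RetentionSummary:
    """Per-marker retentions with class and genome-wide unweighted means."""

    markers: list[MarkerRetention]
    class_means: dict[str, float]
    genome_mean: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "marker_id": m.marker_id,
                    "f": m.f,
                    "n_pos": m.n_pos,
                    "n_neg": m.n_neg,
                    "n_unknown": m.n_unknown,
                }
                for m in self.markers
            ]
        )


@dataclass(frozen=True)
class MethodComparison:
    """Paired t-test between two genotyping methods' per-marker retentions."""

    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    n_markers: int
    degenerate: bool = False
    p_bonferroni: float | None = None


def marker_retention(calls: np.ndarray, marker_id: str = "") -> MarkerRetention:
    """Retention frequency of one matrix row: f = n_pos / (n_pos + n_neg)."""
    calls = np.asarray(calls)
    n_pos = int((calls == PRESENT).sum())
    n_neg = int((calls == ABSENT).sum())
    n_unk = int((calls == UNKNOWN).sum())
    if n_pos + n_neg == 0:
        raise UndefinedRetentionError(
            f"marker {marker_id or '<row>'}: all calls unknown, retention undefined"
        )
    return MarkerRetention(marker_id, n_pos / (n_pos + n_neg), n_pos, n_neg, n_unk)


def class_retention(
    matrix: GenotypeMatrix, markers: Sequence[MarkerRecord]
) -> RetentionSummary:
    """Class means (unweighted over markers) and the genome-wide mean.

    Markers whose rows are entirely unknown are skipped with no contribution;
    classes with no markers are omitted from ``class_means``.
    """
    cls = {m.marker_id: m.chrom_class for m in markers}
    missing = [m for m in matrix.marker_ids if m not in cls]
    if missing:
        raise ValidationError(f"markers without a class label: {missing[:5]}")
    per_marker: list[MarkerRetention] = []
    by_class: dict[str, list[float]] = {}
    for mid, row in zip(matrix.marker_ids, matrix.calls):
        try:
            mr = marker_retention(row, mid)
        except UndefinedRetentionError:
            continue
        per_marker.append(mr)
        by_class.setdefault(cls[mid], []).append(mr.f)
    if not per_marker:
        raise UndefinedRetentionError("no marker with informative calls")
    class_means = {c: float(np.mean(v)) for c, v in by_class.items() if v}
    genome_mean = float(np.mean([m.f for m in per_marker]))
    return RetentionSummary(per_marker, class_means, genome_mean)


def select_hybrids(
    matrix: GenotypeMatrix,
    markers: Sequence[MarkerRecord],
    n_select: int,
    weight_macro: float = 0.5,
) -> list[str]:
    """Pick the hybrids with the best class-weighted marker retention.

    Per-hybrid score = ``weight_macro`` x (fraction of macro markers present)
    + ``(1 - weight_macro)`` x (fraction of micro markers present), among the
    hybrid's informative calls of each class; ties break lexicographically on
    hybrid id.  This mirrors choosing clones with the highest macrochromosome
    retention while keeping good microchromosome values.
    """
    if not 0.0 <= weight_macro <= 1.0:
        raise ValidationError("weight_macro must be in [0, 1]")
    if n_select > matrix.n_hybrids:
        raise ValidationError("n_select exceeds the number of hybrids")
    cls = {m.marker_id: m.chrom_class for m in markers}
    idx_by_class: dict[str, list[int]] = {"macro": [], "micro": []}
    for i, mid in enumerate(matrix.marker_ids):
        c = cls.get(mid)
        if c in idx_by_class:
            idx_by_class[c].append(i)
    if not idx_by_class["macro"] and not idx_by_class["micro"]:
        raise ValidationError("no macro/micro class labels among matrix markers")

    def class_fraction(j: int, rows: list[int]) -> float:
        if not rows:
            return 0.0
        col = matrix.calls[rows, j]
        informative = col != UNKNOWN
        if not informative.any():
            return 0.0
        return float((col[informative] == PRESENT).mean())

    scored = []
    for j, hid in enumerate(matrix.hybrid_ids):
        score = weight_macro * class_fraction(j, idx_by_class["macro"]) + (
            1.0 - weight_macro
        ) * class_fraction(j, idx_by_class["micro"])
        scored.append((-score, hid))
    scored.sort()
    return [hid for _, hid in scored[:n_select]]


def compare_methods(
    retention_a: Sequence[float],
    retention_b: Sequence[float],
    n_comparisons: int = 3,
) -> MethodComparison:
    """Paired two-sided t-test on per-marker retention differences.

    ``n_comparisons`` scales the Bonferroni column (three pairwise tests for
    three methods).  Zero-variance differences yield p = 1 with a degenerate
    flag rather than an error.
    """
    a = np.asarray(retention_a, dtype=float)
    b = np.asarray(retention_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("retention lists must align marker-for-marker")
    if a.size < 2:
        raise ValidationError("need at least 2 markers for a paired t-test")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return MethodComparison(
            mean_a=float(a.mean()),
            mean_b=float(b.mean()),
            t_statistic=0.0,
            p_value=1.0,
            n_markers=a.size,
            degenerate=True,
            p_bonferroni=1.0,
        )
    t, p = stats.ttest_rel(a, b)
    return MethodComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_markers=a.size,
        degenerate=False,
        p_bonferroni=min(1.0, float(p) * n_comparisons),
    )
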