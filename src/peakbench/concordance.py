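"""Interval-level confusion matrix against a reference peak set.

A query condition is scored against a reference by fractional overlap:
query intervals covered by the reference at >= ``min_fraction`` of their own
length are true positives, the rest false positives; true negatives are the
reference-complement intervals similarly recovered by the query complement.
Sensitivity uses the reference peak count as denominator, so it may exceed 1
when the query calls more overlapping peaks than the reference has — this
asymmetric accounting is intentional (see :func:`confusion_counts`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._rounding import round_half_up
from .genome import (
    DEFAULT_MIN_FRACTION,
    GenomeLayout,
    PeakSet,
    complement,
    intersect_fraction,
)

__all__ = [
    "ConfusionCounts",
    "ConcordanceMetrics",
    "ConcordanceSeries",
    "OptimumEstimate",
    "confusion_counts",
    "concordance_metrics",
    "optimum_cell_number",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Interval-level confusion counts for one query condition."""

    query_peaks: int
    reference_peaks: int
    true_positives: int
    false_positives: int
    true_negatives: int

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.true_positives + self.false_positives != self.query_peaks:
            raise ValueError(
                "TP + FP must equal the query peak count "
                f"({self.true_positives} + {self.false_positives} != {self.query_peaks})"
            )


@dataclass(frozen=True)
class ConcordanceMetrics:
    """Sensitivity / specificity / PPV; NaN marks an undefined metric."""

    sensitivity: float
    specificity: float
    ppv: float

    def rounded(self, ndigits: int = 2) -> "ConcordanceMetrics":
        r = lambda v: v if math.isnan(v) else round_half_up(v, ndigits)
        return ConcordanceMetrics(
            sensitivity=r(self.sensitivity),
            specificity=r(self.specificity),
            ppv=r(self.ppv),
        )


@dataclass(frozen=True)
class ConcordanceSeries:
    """(cell number, metrics) pairs with strictly increasing cell numbers."""

    points: tuple[tuple[float, ConcordanceMetrics], ...]

    def __post_init__(self) -> None:
        cells = [c for c, _ in self.points]
        if any(b <= a for a, b in zip(cells, cells[1:])):
            raise ValueError("cell numbers must be strictly increasing")
        if any(c <= 0 for c in cells):
            raise ValueError("cell numbers must be positive")


@dataclass(frozen=True)
class OptimumEstimate:
    """Where the sensitivity and specificity curves cross, if anywhere."""

    crossing_cells: float | None
    plateau: tuple[float, float] | None
    tolerance: float


def confusion_counts(
    query: PeakSet,
    reference: PeakSet,
    layout: GenomeLayout,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> ConfusionCounts:
    """Score *query* against *reference* at a fractional-overlap threshold.

    Both sets should already be merged/normalized by the caller (peak callers
    emit fragmented peaks; merge them first with the pipeline's gap rule).

    TP / FP are counted on the query side: a query interval is a TP iff the
    reference covers >= ``min_fraction`` of its length. TN is the number of
    reference-complement intervals covered by the query complement at the
    same threshold. The reference interval count is carried along as the
    sensitivity denominator.
    """
    if len(reference) == 0:
        raise ValueError("no positives defined: reference peak set is empty")
    hits, misses = intersect_fraction(query, reference, min_fraction=min_fraction)
    ref_comp = complement(reference, layout)
    query_comp = complement(query, layout)
    tn_hits, _ = intersect_fraction(ref_comp, query_comp, min_fraction=min_fraction)
    return ConfusionCounts(
        query_peaks=len(query),
        reference_peaks=len(reference),
        true_positives=len(hits),
        false_positives=len(misses),
        true_negatives=len(tn_hits),
    )


def concordance_metrics(counts: ConfusionCounts) -> ConcordanceMetrics:
    """sensitivity = TP / reference peaks; specificity = TN / (TN + FP);
    PPV = TP / (TP + FP). Zero denominators yield NaN (undefined), never 0.
    """
    tp = counts.true_positives
    fp = counts.false_positives
    tn = counts.true_negatives
    sens = tp / counts.reference_peaks if counts.reference_peaks > 0 else math.nan
    spec = tn / (tn + fp) if (tn + fp) > 0 else math.nan
    ppv = tp / (tp + fp) if (tp + fp) > 0 else math.nan
    return ConcordanceMetrics(sensitivity=sens, specificity=spec, ppv=ppv)


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round_half_up(x / 10 ** (exp - sig + 1)) * 10 ** (exp - sig + 1)


def optimum_cell_number(
    series: ConcordanceSeries, tolerance: float = 0.02
) -> OptimumEstimate:
    """Locate where sensitivity and specificity cross, interpolating in log10(cells).

    Both curves are treated as piecewise linear in log10 of the cell number.
    The crossing is solved inside the highest segment where sens - spec
    changes sign; the plateau is the maximal surrounding range where the two
    curves stay within *tolerance* of each other, reported rounded to two
    significant figures. If the curves never cross the estimate is empty; if
    they coincide everywhere the crossing degenerates to the smallest cell
    number and the plateau spans the full range.
    """
    if len(series.points) < 2:
        raise ValueError("optimum finding requires at least 2 points")
    cells = np.array([c for c, _ in series.points], dtype=float)
    sens = np.array([m.sensitivity for _, m in series.points], dtype=float)
    spec = np.array([m.specificity for _, m in series.points], dtype=float)
    t = np.log10(cells)
    d = sens - spec

    if np.all(d == 0):
        lo, hi = float(cells[0]), float(cells[-1])
        return OptimumEstimate(
            crossing_cells=lo, plateau=(lo, hi), tolerance=tolerance
        )

    t_cross: float | None = None
    for i in range(len(t) - 2, -1, -1):
        d0, d1 = d[i], d[i + 1]
        if min(d0, d1) <= 0.0 <= max(d0, d1):
            if d0 == d1 == 0.0:
                t_cross = float(t[i])
            elif d0 == d1:
                continue
            else:
                t_cross = float(t[i] + (t[i + 1] - t[i]) * d0 / (d0 - d1))
            break
    if t_cross is None:
        return OptimumEstimate(crossing_cells=None, plateau=None, tolerance=tolerance)

    grid = np.linspace(t[0], t[-1], 4001)
    gap = np.interp(grid, t, sens) - np.interp(grid, t, spec)
    within = np.abs(gap) <= tolerance
    k = int(np.argmin(np.abs(grid - t_cross)))
    if not within[k]:
        within[k] = True  # crossing itself always belongs to its plateau
    lo_k, hi_k = k, k
    while lo_k > 0 and within[lo_k - 1]:
        lo_k -= 1
    while hi_k < len(grid) - 1 and within[hi_k + 1]:
        hi_k += 1
    plateau = (
        _round_sig(10 ** grid[lo_k]),
        _round_sig(10 ** grid[hi_k]),
    )
    return OptimumEstimate(
        crossing_cells=float(10 ** t_cross), plateau=plateau, tolerance=tolerance
    )
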