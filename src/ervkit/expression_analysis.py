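"""Downstream analyses of per-element expression.

Covers element-internal coverage profiles normalized to the 5'LTR, top-k
expression concentration, differentiation trajectories normalized to a
housekeeping series, rank/linear correlation between trajectories, and
transcription-factor proximity/ordering relative to element TSSs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ervkit.association import (
    associate_from_distances,
    control_distances,
    nearest_point_distance,
)
from ervkit.core_io import (
    AlignmentRecord,
    MarkerPeakSet,
    ProvirusRecord,
    REGION_ORDER,
)
from ervkit.quantification import ElementExpression


@dataclass
class RegionCoverageProfile:
    element_id: str
    counts: Dict[str, float]       # region label -> assigned read mass
    normalized: Dict[str, float]   # counts / counts["5LTR"]
    defined: bool                  # False when the 5'LTR count is zero


@dataclass
class StageSeries:
    """Expression across ordered differentiation stages with a housekeeping
    normalizer series."""

    stages: List[str]
    values: np.ndarray
    normalizer: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.normalizer = np.asarray(self.normalizer, dtype=float)
        if len(self.values) != len(self.stages):
            raise ValueError("values must align with stages")
        if len(self.normalizer) != len(self.stages):
            raise ValueError("normalizer must align with stages")


@dataclass
class TFProximityResult:
    tf: str
    mean_distance_bp: float            # over elements with a peak within max_bp
    n_bound: int
    n_total: int
    mean_distance_all_bp: float        # over all elements with any finite distance
    windows: Optional[np.ndarray] = None
    f_curve: Optional[np.ndarray] = None
    max_assoc_window_bp: Optional[int] = None
    half_window_ratio: Optional[float] = None  # diagnostic: mean / max-assoc window


def region_coverage(alignments: Iterable[AlignmentRecord],
                    element: ProvirusRecord,
                    assignments: Optional[Dict[str, np.ndarray]] = None
                    ) -> RegionCoverageProfile:
    """Assigned read mass per internal region, normalized to the 5'LTR.

    Unique reads count fully; multireads use the probability vector in
    `assignments` (read_id -> per-hit probabilities) or a uniform split.
    """
    if not element.regions or "5LTR" not in element.regions:
        raise ValueError(f"element {element.element_id} has no 5LTR region map")
    counts = {label: 0.0 for label in REGION_ORDER if label in element.regions}
    for rec in alignments:
        if rec.is_unique:
            probs = [1.0]
        else:
            p = None if assignments is None else assignments.get(rec.read_id)
            probs = p if p is not None else [1.0 / len(rec.hits)] * len(rec.hits)
        for hit, p in zip(rec.hits, probs):
            if hit.chrom != element.chrom:
                continue
            mid = hit.midpoint
            for label, sub in element.regions.items():
                if sub.contains(mid):
                    counts[label] += rec.weight * float(p)
                    break
    ltr = counts["5LTR"]
    defined = ltr > 0
    normalized = {
        label: (c / ltr if defined else math.nan) for label, c in counts.items()
    }
    return RegionCoverageProfile(element_id=element.element_id, counts=counts,
                                 normalized=normalized, defined=defined)


def top_k_concentration(expressions: Sequence[ElementExpression], k: int
                        ) -> Tuple[List[ElementExpression], float]:
    """Top-k elements by RPKM (ties broken by element_id) and the fraction
    of total RPKM they account for."""
    if not expressions:
        raise ValueError("empty expression list")
    if not 1 <= k <= len(expressions):
        raise ValueError(f"k={k} out of range [1, {len(expressions)}]")
    ordered = sorted(expressions, key=lambda e: (-e.rpkm, e.element_id))
    total = sum(e.rpkm for e in expressions)
    top = ordered[:k]
    fraction = sum(e.rpkm for e in top) / total if total > 0 else 0.0
    return top, fraction


def normalize_trajectory(series: StageSeries) -> np.ndarray:
    """values / normalizer per stage, rescaled so stage 0 equals 1."""
    if np.any(series.normalizer <= 0):
        raise ValueError("normalizer must be strictly positive at every stage")
    ratio = series.values / series.normalizer
    if ratio[0] == 0:
        return ratio
    return ratio / ratio[0]


def correlate_trajectories(x: Sequence[float], y: Sequence[float],
                           method: str = "spearman") -> float:
    """Correlation between two stage series; NaN (with a warning) for a
    constant series, never an exception."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 stages")
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined for a constant series")
        return math.nan
    if method == "spearman":
        rho, _ = stats.spearmanr(x, y)
    else:
        rho, _ = stats.pearsonr(x, y)
    return float(rho)


def tss_distances(elements: Sequence[ProvirusRecord],
                  peaks: MarkerPeakSet) -> np.ndarray:
    """Distance of the nearest peak to each element's strand-aware TSS."""
    return np.array([
        nearest_point_distance(el.tss, peaks.positions(el.chrom))
        for el in elements
    ])


def tf_proximity(elements: Sequence[ProvirusRecord], peaks: MarkerPeakSet,
                 controls=None, bin_bp: int = 500, max_bp: int = 10_000,
                 subset: Optional[Sequence[str]] = None) -> TFProximityResult:
    """Mean nearest-peak distance to element TSSs, plus an F-vs-distance
    curve when control loci are supplied.

    Elements without a peak within `max_bp` are excluded from the headline
    mean (their count is reported); the mean over all elements with any
    peak on their chromosome is reported alongside.  The half-window ratio
    (mean distance over the window of maximal F) is a diagnostic for the
    uniform-placement model, in which peaks uniform in [0, D] give a mean
    of D/2.
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be positive")
    if subset is not None:
        keep = set(subset)
        elements = [el for el in elements if el.element_id in keep]
    if not elements:
        raise ValueError("empty element subset")
    dists = tss_distances(elements, peaks)
    bound = dists <= max_bp
    finite = np.isfinite(dists)
    if not bound.any():
        raise ValueError(f"no element has a peak within {max_bp} bp of its TSS")
    mean_bound = float(dists[bound].mean())
    mean_all = float(dists[finite].mean()) if finite.any() else math.inf

    windows = f_curve = None
    max_w = None
    ratio = None
    if controls is not None:
        windows = np.arange(bin_bp, max_bp + 1, bin_bp, dtype=np.int64)
        ctrl = control_distances(controls, peaks)
        f_curve = np.array([
            associate_from_distances(dists, ctrl, int(w)).f_score
            for w in windows
        ])
        max_w = int(windows[int(np.argmax(f_curve))])
        ratio = mean_bound / max_w if max_w > 0 else math.nan
    return TFProximityResult(
        tf=peaks.marker, mean_distance_bp=mean_bound,
        n_bound=int(bound.sum()), n_total=len(elements),
        mean_distance_all_bp=mean_all, windows=windows, f_curve=f_curve,
        max_assoc_window_bp=max_w, half_window_ratio=ratio)


def tf_order_fraction(elements: Sequence[ProvirusRecord],
                      peak_sets: Sequence[MarkerPeakSet],
                      max_bp: int = 10_000) -> Tuple[float, int, int]:
    """Fraction of elements whose nearest-peak TSS distances are strictly
    increasing in the given factor order.

    Elements missing a peak within max_bp for any factor are excluded;
    returns (fraction, n_included, n_excluded).  Ties count as violations.
    """
    if len(peak_sets) < 2:
        raise ValueError("need at least two factors to order")
    n_included = 0
    n_ordered = 0
    n_excluded = 0
    for el in elements:
        dists = [nearest_point_distance(el.tss, ps.positions(el.chrom))
                 for ps in peak_sets]
        if any(d > max_bp for d in dists):
            n_excluded += 1
            continue
        n_included += 1
        if all(a < b for a, b in zip(dists, dists[1:])):
            n_ordered += 1
    fraction = n_ordered / n_included if n_included else 0.0
    return fraction, n_included, n_excluded


def binding_fraction(elements: Sequence[ProvirusRecord],
                     peaks: MarkerPeakSet, window_bp: int,
                     anchor: str = "TSS") -> float:
    """Fraction of elements with at least one peak within window_bp of the
    anchor: the TSS point, or the 5'LTR sub-interval (edge distance, 0
    inside) when anchor="LTR5" and a region map is present."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if anchor not in ("TSS", "LTR5"):
        raise ValueError(f"unknown anchor {anchor!r}")
    if not elements:
        raise ValueError("empty element list")
    n_bound = 0
    for el in elements:
        arr = peaks.positions(el.chrom)
        if anchor == "LTR5" and el.regions and "5LTR" in el.regions:
            sub = el.regions["5LTR"]
            d = _interval_point_min_distance(sub.start, sub.end, arr)
        else:
            d = nearest_point_distance(el.tss, arr)
        if d <= window_bp:
            n_bound += 1
    return n_bound / len(elements)


def _interval_point_min_distance(start: int, end: int,
                                 positions: np.ndarray) -> float:
    if len(positions) == 0:
        return math.inf
    i = int(np.searchsorted(positions, start, side="left"))
    if i < len(positions) and int(positions[i]) < end:
        return 0.0
    best = math.inf
    if i > 0:
        best = start - int(positions[i - 1])
    j = int(np.searchsorted(positions, end, side="left"))
    if j < len(positions):
        best = min(best, int(positions[j]) - end)
    return float(best)
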