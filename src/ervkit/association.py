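"""Proximity association between element loci and marker peak positions.

An element is "associated" with a marker when some peak lies within a fixed
window of its nearer edge (distance 0 inside the element).  Association
strength is the beta-weighted harmonic mean of precision and sensitivity
against a set of random control positions, with significance from a
one-sided Fisher exact test computed in log space so that extreme
enrichments do not underflow.

Precision and sensitivity are computed from *rates* (within-fraction of
elements vs. within-fraction of controls), not raw counts, so the score is
invariant to the size of the control set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from ervkit.core_io import ChromSizes, MarkerPeakSet, ProvirusRecord

DEFAULT_WINDOW = 2_000
DEFAULT_BETA = 0.5
DEFAULT_N_CONTROLS = 100_000
DEFAULT_STEP = 500
DEFAULT_WMAX = 10_000

SIGNIFICANCE_LINE = 0.5

ControlLoci = List[Tuple[str, int]]


@dataclass
class AssociationResult:
    window_bp: int
    n_elements: int
    n_elements_within: int
    n_controls: int
    n_controls_within: int
    precision: float
    sensitivity: float
    beta: float
    f_score: float
    log_p: float

    def __post_init__(self) -> None:
        assert self.n_elements_within <= self.n_elements
        assert self.n_controls_within <= self.n_controls
        assert self.log_p <= 0.0


@dataclass
class AssociationProfile:
    cell_type: str
    marker: str
    windows: np.ndarray
    f_scores: np.ndarray

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=np.int64)
        self.f_scores = np.asarray(self.f_scores, dtype=float)
        if self.windows.shape != self.f_scores.shape:
            raise ValueError("windows and f_scores must align")
        if len(self.windows) > 1 and not np.all(np.diff(self.windows) > 0):
            raise ValueError("windows must be strictly increasing")


def distance_element_to_marker(element: ProvirusRecord, position: int) -> int:
    """Distance from a peak position to the nearer element edge.

    Equals min(|start - m|, |end - m|) outside the element and 0 inside
    (the center form |center - m| - length/2 is negative there and is
    clamped).
    """
    iv = element.interval
    if iv.contains(position):
        return 0
    return min(abs(iv.start - position), abs(iv.end - position))


def nearest_point_distance(position: int, positions: np.ndarray) -> float:
    """Distance from a point to the nearest of sorted positions; inf if none."""
    n = len(positions)
    if n == 0:
        return math.inf
    i = int(np.searchsorted(positions, position))
    best = math.inf
    if i < n:
        best = abs(int(positions[i]) - position)
    if i > 0:
        best = min(best, abs(position - int(positions[i - 1])))
    return float(best)


def nearest_marker_distance(element: ProvirusRecord,
                            peaks: MarkerPeakSet) -> float:
    """Minimum edge distance to any peak on the element's chromosome.

    Binary search over the sorted positions; +inf when the chromosome has
    no peaks.
    """
    arr = peaks.positions(element.chrom)
    n = len(arr)
    if n == 0:
        return math.inf
    iv = element.interval
    lo = int(np.searchsorted(arr, iv.start, side="left"))
    if lo < n and int(arr[lo]) < iv.end:  # a peak inside the element
        return 0.0
    best = math.inf
    if lo > 0:
        best = iv.start - int(arr[lo - 1])
    hi = int(np.searchsorted(arr, iv.end, side="left"))
    if hi < n:
        best = min(best, int(arr[hi]) - iv.end)
    return float(best)


def element_distances(elements: Sequence[ProvirusRecord],
                      peaks: MarkerPeakSet) -> np.ndarray:
    return np.array([nearest_marker_distance(e, peaks) for e in elements])


def control_distances(controls: ControlLoci, peaks: MarkerPeakSet) -> np.ndarray:
    out = np.empty(len(controls))
    for i, (chrom, pos) in enumerate(controls):
        out[i] = nearest_point_distance(pos, peaks.positions(chrom))
    return out


def generate_control_loci(sizes: ChromSizes, n: int = DEFAULT_N_CONTROLS,
                          seed: Optional[int] = None,
                          rng: Optional[np.random.Generator] = None
                          ) -> ControlLoci:
    """Draw n positions uniformly over the genome (chromosomes weighted by
    length).  Deterministic given seed."""
    if n < 1:
        raise ValueError("need at least one control locus")
    if rng is None:
        rng = np.random.default_rng(seed)
    names = list(sizes)
    lengths = np.array([sizes[c] for c in names], dtype=float)
    chrom_idx = rng.choice(len(names), size=n, p=lengths / lengths.sum())
    out: ControlLoci = []
    for i in chrom_idx:
        out.append((names[i], int(rng.integers(0, sizes[names[i]]))))
    return out


def f_beta(precision: float, sensitivity: float,
           beta: float = DEFAULT_BETA) -> float:
    """(1 + b^2) P R / (b^2 P + R); 0 when both P and R are 0."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= sensitivity <= 1.0):
        raise ValueError("precision and sensitivity must be in [0, 1]")
    if beta <= 0:
        raise ValueError("beta must be positive")
    denom = beta * beta * precision + sensitivity
    if denom == 0.0:
        return 0.0
    return (1.0 + beta * beta) * precision * sensitivity / denom


def log_fisher_greater(n_elements_within: int, n_elements: int,
                       n_controls_within: int, n_controls: int) -> float:
    """Natural-log one-sided (enrichment) Fisher exact p for the 2x2 table
    {element, control} x {within, not within}.

    Summed in log space over the hypergeometric upper tail, so p values far
    below float underflow remain representable.
    """
    N = n_elements + n_controls
    K = n_elements_within + n_controls_within
    k_obs = n_elements_within
    k_max = min(K, n_elements)
    if k_obs > k_max:
        raise ValueError("inconsistent 2x2 table")
    ks = np.arange(k_obs, k_max + 1)
    if len(ks) == 0:
        return 0.0
    log_terms = hypergeom.logpmf(ks, N, K, n_elements)
    log_terms = log_terms[np.isfinite(log_terms)]
    if len(log_terms) == 0:
        return -math.inf
    return float(min(0.0, logsumexp(log_terms)))


def associate_from_distances(elem_dist: np.ndarray, ctrl_dist: np.ndarray,
                             window_bp: int = DEFAULT_WINDOW,
                             beta: float = DEFAULT_BETA) -> AssociationResult:
    """Build the association statistic from precomputed nearest distances."""
    n_e = len(elem_dist)
    n_c = len(ctrl_dist)
    if n_e == 0:
        raise ValueError("no elements")
    if n_c == 0:
        raise ValueError("no controls")
    e_within = int(np.count_nonzero(elem_dist <= window_bp))
    c_within = int(np.count_nonzero(ctrl_dist <= window_bp))
    rate_tp = e_within / n_e
    rate_fp = c_within / n_c
    sensitivity = rate_tp
    precision = rate_tp / (rate_tp + rate_fp) if (rate_tp + rate_fp) > 0 else 0.0
    return AssociationResult(
        window_bp=window_bp,
        n_elements=n_e,
        n_elements_within=e_within,
        n_controls=n_c,
        n_controls_within=c_within,
        precision=precision,
        sensitivity=sensitivity,
        beta=beta,
        f_score=f_beta(precision, sensitivity, beta),
        log_p=log_fisher_greater(e_within, n_e, c_within, n_c),
    )


def associate(elements: Sequence[ProvirusRecord], peaks: MarkerPeakSet,
              controls: ControlLoci, window_bp: int = DEFAULT_WINDOW,
              beta: float = DEFAULT_BETA) -> AssociationResult:
    """Classify elements and control points against the window and score."""
    if not elements:
        raise ValueError("no elements")
    if window_bp <= 0:
        raise ValueError("window must be positive")
    return associate_from_distances(
        element_distances(elements, peaks),
        control_distances(controls, peaks),
        window_bp=window_bp, beta=beta)


def association_profile(elements: Sequence[ProvirusRecord],
                        peaks: MarkerPeakSet, controls: ControlLoci,
                        w_max: int = DEFAULT_WMAX, step: int = DEFAULT_STEP,
                        beta: float = DEFAULT_BETA,
                        cell_type: str = "", marker: str = ""
                        ) -> AssociationProfile:
    """F score at each window in {step, 2*step, ..., w_max}.

    Distances are computed once and thresholded per window.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if w_max < step:
        raise ValueError("w_max must be >= step")
    windows = np.arange(step, w_max + 1, step, dtype=np.int64)
    elem_dist = element_distances(elements, peaks)
    ctrl_dist = control_distances(controls, peaks)
    scores = np.array([
        associate_from_distances(elem_dist, ctrl_dist, int(w), beta).f_score
        for w in windows
    ])
    return AssociationProfile(cell_type=cell_type or peaks.cell_type,
                              marker=marker or peaks.marker,
                              windows=windows, f_scores=scores)


def result_to_dict(res: AssociationResult) -> Dict[str, float]:
    return {
        "window_bp": res.window_bp,
        "n_elements": res.n_elements,
        "n_elements_within": res.n_elements_within,
        "n_controls": res.n_controls,
        "n_controls_within": res.n_controls_within,
        "precision": res.precision,
        "sensitivity": res.sensitivity,
        "beta": res.beta,
        "f_score": res.f_score,
        "log_p": res.log_p,
    }
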