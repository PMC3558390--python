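"""Repeat-element expression from alignment records.

Two-pass procedure: pass 1 counts uniquely mapping reads (hit midpoint
rule); pass 2 distributes each multiread across its candidate hits with
probability proportional to the unique-read count of each hit's context
region (the flanking window minus the hit itself).  Elements then get
RPKM = 1e6 * N_r / (L_kb * N_T) and a specific-vs-unspecific transcription
estimate U(s) = R(c)/2, T(s) = max(0, R(s) - U(s)), with context counts
normalized to the element's length scale before the subtraction.

Multireads are assigned in a single probabilistic round (no EM); reads with
all-zero context counts are split uniformly.  N_T counts each read once,
regardless of its number of hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ervkit.core_io import (
    AlignmentRecord,
    ChromSizes,
    GenomicInterval,
    ProvirusRecord,
)

DEFAULT_FLANK = 10_000


@dataclass
class ContextRegion:
    """Flanking region of a target interval: [start-n, start) + [end, end+n),
    clipped to the chromosome and minus any exclusion intervals."""

    target: GenomicInterval
    flank_bp: int
    flanks: List[GenomicInterval] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(f.length for f in self.flanks)


@dataclass
class ElementExpression:
    element_id: str
    family: str
    length_kb: float
    n_reads: float          # N_r: unique + reassigned multiread mass
    rpkm: float
    r_s: float              # read count over the element
    r_c: float              # context count, normalized to the 2x-element-length scale
    u_s: float              # unspecific estimate r_c / 2
    t_s: float              # specific estimate max(0, r_s - u_s)
    specificity: float      # t_s / r_s (0 when r_s == 0)
    unique_reads: float = 0.0
    multi_mass: float = 0.0


@dataclass
class QuantificationResult:
    expressions: List[ElementExpression]
    n_total_reads: int
    n_unique_reads: int
    n_multireads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.expressions])


def make_context(target: GenomicInterval, flank_bp: int, sizes: ChromSizes,
                 exclusions: Optional[Sequence[GenomicInterval]] = None
                 ) -> ContextRegion:
    """Build the two flanking intervals of a target, clipped to chromosome
    bounds and with exclusion intervals subtracted.  A fully clipped
    context (length 0) is legal."""
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    chrom_len = sizes[target.chrom]
    raw: List[Tuple[int, int]] = []
    left = (max(0, target.start - flank_bp), target.start)
    right = (target.end, min(chrom_len, target.end + flank_bp))
    for s, e in (left, right):
        if s < e:
            raw.append((s, e))
    if exclusions:
        cuts = sorted(
            (x.start, x.end) for x in exclusions if x.chrom == target.chrom
        )
        raw = _subtract(raw, cuts)
    flanks = [GenomicInterval(target.chrom, s, e) for s, e in raw]
    return ContextRegion(target=target, flank_bp=flank_bp, flanks=flanks)


def _subtract(pieces: List[Tuple[int, int]],
              cuts: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    for s, e in pieces:
        segments = [(s, e)]
        for cs, ce in cuts:
            next_segments = []
            for ss, se in segments:
                if ce <= ss or cs >= se:
                    next_segments.append((ss, se))
                    continue
                if ss < cs:
                    next_segments.append((ss, cs))
                if ce < se:
                    next_segments.append((ce, se))
            segments = next_segments
        out.extend(segments)
    return out


class _MassIndex:
    """Sorted per-chromosome positions with prefix-summed weights, for O(log n)
    weighted counts over intervals."""

    def __init__(self, hits: Dict[str, List[Tuple[int, float]]]):
        self._pos: Dict[str, np.ndarray] = {}
        self._cum: Dict[str, np.ndarray] = {}
        for chrom, pairs in hits.items():
            pairs.sort(key=lambda t: t[0])
            pos = np.array([p for p, _ in pairs], dtype=np.int64)
            w = np.array([w for _, w in pairs], dtype=float)
            self._pos[chrom] = pos
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(w)])

    def mass_in(self, chrom: str, start: int, end: int) -> float:
        pos = self._pos.get(chrom)
        if pos is None or len(pos) == 0:
            return 0.0
        i = int(np.searchsorted(pos, start, side="left"))
        j = int(np.searchsorted(pos, end, side="left"))
        return float(self._cum[chrom][j] - self._cum[chrom][i])

    def mass_in_intervals(self, intervals: Iterable[GenomicInterval]) -> float:
        return sum(self.mass_in(iv.chrom, iv.start, iv.end) for iv in intervals)


class _ElementLocator:
    """Find the element containing a position (elements non-overlapping)."""

    def __init__(self, elements: Sequence[ProvirusRecord]):
        by_chrom: Dict[str, List[Tuple[int, int, int]]] = {}
        for idx, el in enumerate(elements):
            by_chrom.setdefault(el.chrom, []).append(
                (el.interval.start, el.interval.end, idx))
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        self._idx: Dict[str, np.ndarray] = {}
        for chrom, triples in by_chrom.items():
            triples.sort()
            for (s1, e1, _), (s2, _, _) in zip(triples, triples[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"overlapping elements on {chrom}: resolve overlaps "
                        "or supply exclusion sets")
            self._starts[chrom] = np.array([t[0] for t in triples], dtype=np.int64)
            self._ends[chrom] = np.array([t[1] for t in triples], dtype=np.int64)
            self._idx[chrom] = np.array([t[2] for t in triples], dtype=np.int64)

    def locate(self, chrom: str, position: int) -> int:
        """Index of the containing element, or -1."""
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return -1
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i >= 0 and position < self._ends[chrom][i]:
            return int(self._idx[chrom][i])
        return -1


def reassign_multiread(context_counts: Sequence[float]) -> np.ndarray:
    """Probability of each candidate hit, proportional to the unique-read
    count of its context; uniform when every context count is zero."""
    counts = np.asarray(context_counts, dtype=float)
    if len(counts) == 0:
        raise ValueError("empty context count vector")
    if np.any(counts < 0):
        raise ValueError("negative context counts")
    total = counts.sum()
    if total == 0.0:
        return np.full(len(counts), 1.0 / len(counts))
    return counts / total


def count_reads(alignments: Iterable[AlignmentRecord], region: GenomicInterval,
                mode: str = "unique_only",
                assignments: Optional[Dict[str, np.ndarray]] = None) -> float:
    """Weighted read count over a region by the hit-midpoint rule.

    unique_only sums unique records only; all_assigned additionally sums
    the fractional multiread mass given by `assignments`
    (read_id -> per-hit probability vector; uniform split when absent).
    """
    if mode not in ("unique_only", "all_assigned"):
        raise ValueError(f"unknown counting mode {mode!r}")
    total = 0.0
    for rec in alignments:
        if rec.is_unique:
            hit = rec.hits[0]
            if hit.chrom == region.chrom and region.contains(hit.midpoint):
                total += rec.weight
        elif mode == "all_assigned":
            probs = None if assignments is None else assignments.get(rec.read_id)
            if probs is None:
                probs = np.full(len(rec.hits), 1.0 / len(rec.hits))
            for hit, p in zip(rec.hits, probs):
                if hit.chrom == region.chrom and region.contains(hit.midpoint):
                    total += rec.weight * float(p)
    return total


def specific_expression(r_s: float, r_c: float) -> Tuple[float, float, float]:
    """Unspecific estimate u = r_c/2, specific t = max(0, r_s - u), and
    specificity t/r_s (0 when r_s is 0).  r_c must already be on the same
    length scale as r_s (two element-lengths of context)."""
    if r_s < 0 or r_c < 0:
        raise ValueError("read counts must be non-negative")
    u_s = r_c / 2.0
    t_s = max(0.0, r_s - u_s)
    specificity = t_s / r_s if r_s > 0 else 0.0
    return u_s, t_s, specificity


def quantify(alignments: Iterable[AlignmentRecord],
             elements: Sequence[ProvirusRecord],
             sizes: ChromSizes,
             flank_bp: int = DEFAULT_FLANK,
             exclude_elements_from_context: bool = True
             ) -> QuantificationResult:
    """Quantify every element from an alignment stream.

    Pass 1 indexes unique-read midpoints and counts them per element;
    pass 2 reassigns each multiread across its hits by context-weighted
    probability and accumulates fractional mass onto the containing
    elements.  Context counts for the specificity correction exclude other
    annotated elements when `exclude_elements_from_context` is set (so
    sister copies do not contaminate the local background estimate).
    """
    records = list(alignments)
    n_total = len(records)
    if n_total == 0:
        raise ValueError("no reads: N_T = 0")

    locator = _ElementLocator(elements)

    unique_hits: Dict[str, List[Tuple[int, float]]] = {}
    unique_mass = np.zeros(len(elements))
    n_unique = 0
    for rec in records:
        if not rec.is_unique:
            continue
        n_unique += 1
        hit = rec.hits[0]
        mid = hit.midpoint
        unique_hits.setdefault(hit.chrom, []).append((mid, rec.weight))
        idx = locator.locate(hit.chrom, mid)
        if idx >= 0:
            unique_mass[idx] += rec.weight
    unique_index = _MassIndex(unique_hits)

    multi_hits: Dict[str, List[Tuple[int, float]]] = {}
    multi_mass = np.zeros(len(elements))
    n_multi = 0
    for rec in records:
        if rec.is_unique:
            continue
        n_multi += 1
        ctx_counts = []
        for hit in rec.hits:
            lo = max(0, hit.start - flank_bp)
            hi = min(sizes[hit.chrom], hit.end + flank_bp)
            inside = unique_index.mass_in(hit.chrom, hit.start, hit.end)
            ctx_counts.append(
                unique_index.mass_in(hit.chrom, lo, hi) - inside)
        probs = reassign_multiread(ctx_counts)
        for hit, p in zip(rec.hits, probs):
            mass = rec.weight * float(p)
            if mass == 0.0:
                continue
            mid = hit.midpoint
            multi_hits.setdefault(hit.chrom, []).append((mid, mass))
            idx = locator.locate(hit.chrom, mid)
            if idx >= 0:
                multi_mass[idx] += mass
    multi_index = _MassIndex(multi_hits)

    expressions: List[ElementExpression] = []
    intervals = [el.interval for el in elements]
    for i, el in enumerate(elements):
        exclusions = None
        if exclude_elements_from_context:
            exclusions = [iv for j, iv in enumerate(intervals) if j != i]
        ctx = make_context(el.interval, flank_bp, sizes, exclusions=exclusions)
        r_s = float(unique_mass[i] + multi_mass[i])
        raw_c = (unique_index.mass_in_intervals(ctx.flanks)
                 + multi_index.mass_in_intervals(ctx.flanks))
        # rescale the context count to two element-lengths so U(s) = r_c/2
        # is an expected count over the element itself
        if ctx.length > 0:
            r_c = raw_c * (2.0 * el.interval.length) / ctx.length
        else:
            r_c = 0.0
        u_s, t_s, spec = specific_expression(r_s, r_c)
        length_kb = el.interval.length / 1_000.0
        rpkm = 1.0e6 * r_s / (length_kb * n_total)
        expressions.append(ElementExpression(
            element_id=el.element_id, family=el.family, length_kb=length_kb,
            n_reads=r_s, rpkm=rpkm, r_s=r_s, r_c=r_c, u_s=u_s, t_s=t_s,
            specificity=spec, unique_reads=float(unique_mass[i]),
            multi_mass=float(multi_mass[i])))
    return QuantificationResult(expressions=expressions, n_total_reads=n_total,
                                n_unique_reads=n_unique, n_multireads=n_multi)


def aggregate_family(result: QuantificationResult,
                     family_map: Optional[Dict[str, str]] = None
                     ) -> pd.DataFrame:
    """Per-family cumulative RPKM and fraction of total reads.

    `family_map` optionally collapses element families into display groups
    (e.g. every "HERV-*" family into "HERV").
    """
    rows: Dict[str, Dict[str, float]] = {}
    for e in result.expressions:
        fam = e.family
        if family_map is not None:
            fam = family_map.get(fam, fam)
        agg = rows.setdefault(fam, {"rpkm": 0.0, "n_reads": 0.0})
        agg["rpkm"] += e.rpkm
        agg["n_reads"] += e.n_reads
    df = pd.DataFrame([
        {"family": fam, "rpkm": agg["rpkm"],
         "read_fraction": agg["n_reads"] / result.n_total_reads}
        for fam, agg in rows.items()
    ])
    return df.sort_values("rpkm", ascending=False).reset_index(drop=True)
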