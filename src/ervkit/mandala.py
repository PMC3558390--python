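"""Polar per-chromosome scatter plots ("mandalas").

Linear chromosome position maps to angle; distance to the nearest marker
maps to radius on a log scale from the perimeter (distance 0) to the
center (distance >= d_max, default 1 Mb).  Dots inside the association
window are drawn blue, the rest red; dot area optionally scales with
expression, and elements with a peak inside the 5'LTR window can carry a
green ring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from ervkit.association import nearest_marker_distance, nearest_point_distance
from ervkit.core_io import ChromSizes, MarkerPeakSet, ProvirusRecord

DEFAULT_DMAX = 1_000_000
DEFAULT_WINDOW = 2_000

COLOR_WITHIN = "#2040c0"
COLOR_BEYOND = "#c03030"
COLOR_RING = "#30a050"


@dataclass
class MandalaDot:
    element_id: str
    angle_rad: float
    radius: float
    color_class: str            # "within" or "beyond"
    size: float = 1.0           # dot area scale (proportional to expression)
    ring_mark: bool = False     # peak inside the 5'LTR window

    def __post_init__(self) -> None:
        if not 0.0 <= self.angle_rad < 2.0 * math.pi + 1e-12:
            raise ValueError("angle out of [0, 2*pi)")
        if not 0.0 <= self.radius <= 1.0:
            raise ValueError("radius out of [0, 1]")
        if self.color_class not in ("within", "beyond"):
            raise ValueError(f"bad color class {self.color_class!r}")


def mandala_coords(position: int, chrom_len: int, distance: float,
                   d_max: float = DEFAULT_DMAX) -> Tuple[float, float]:
    """Map (chromosomal position, marker distance) to (angle, radius).

    angle = 2*pi*position/chrom_len; radius = 1 - log(1+d)/log(1+d_max),
    clamped to [0, 1] so distance 0 sits on the perimeter and distances
    beyond d_max collapse to the center.
    """
    if chrom_len <= 0:
        raise ValueError("chromosome length must be positive")
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    if not 0 <= position <= chrom_len:
        raise ValueError("position outside chromosome")
    angle = 2.0 * math.pi * position / chrom_len
    if angle >= 2.0 * math.pi:
        angle = 0.0
    if math.isinf(distance):
        radius = 0.0
    else:
        radius = 1.0 - math.log1p(max(0.0, distance)) / math.log1p(d_max)
        radius = min(1.0, max(0.0, radius))
    return angle, radius


def make_dots(elements: Sequence[ProvirusRecord], peaks: MarkerPeakSet,
              chrom: str, sizes: ChromSizes,
              window_bp: int = DEFAULT_WINDOW, d_max: float = DEFAULT_DMAX,
              expression: Optional[Dict[str, float]] = None,
              ltr_window_bp: int = 500) -> List[MandalaDot]:
    """Build dots for every element on one chromosome.

    `expression` (element_id -> RPKM) switches on area scaling with
    sqrt-of-expression so area, not diameter, tracks the value.
    """
    chrom_len = sizes[chrom]
    dots: List[MandalaDot] = []
    for el in elements:
        if el.chrom != chrom:
            continue
        d = nearest_marker_distance(el, peaks)
        angle, radius = mandala_coords(el.interval.midpoint, chrom_len, d, d_max)
        size = 1.0
        if expression is not None:
            size = math.sqrt(max(0.0, expression.get(el.element_id, 0.0)))
        ring = nearest_point_distance(el.tss, peaks.positions(chrom)) <= ltr_window_bp
        dots.append(MandalaDot(
            element_id=el.element_id, angle_rad=angle, radius=radius,
            color_class="within" if d <= window_bp else "beyond",
            size=size, ring_mark=bool(ring)))
    return dots


def render_mandala(dots: Sequence[MandalaDot], chrom: str, out=None,
                   f_score: Optional[float] = None,
                   size_scaling: bool = True, base_area: float = 40.0):
    """Render dots as a polar scatter; write PNG or SVG when `out` is given
    (format by extension), else return the open (figure, axes) pair."""
    if not dots:
        warnings.warn(f"no dots for {chrom}: rendering empty mandala")
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    ax.set_ylim(0, 1.05)
    ax.set_yticks([])
    ax.set_xticks([])
    if dots:
        angles = np.array([d.angle_rad for d in dots])
        radii = np.array([d.radius for d in dots])
        colors = [COLOR_WITHIN if d.color_class == "within" else COLOR_BEYOND
                  for d in dots]
        if size_scaling:
            sizes = np.array([d.size for d in dots])
            smax = sizes.max()
            areas = base_area * (0.2 + sizes / smax) if smax > 0 \
                else np.full(len(dots), base_area)
        else:
            areas = np.full(len(dots), base_area)
        edge = [COLOR_RING if d.ring_mark else "none" for d in dots]
        ax.scatter(angles, radii, s=areas, c=colors, edgecolors=edge,
                   linewidths=1.2, zorder=3, gid="mandala_dots")
    title = chrom
    if f_score is not None:
        title += f"\nF = {f_score:.2f}"
    ax.set_title(title, pad=14)
    if out is None:
        return fig, ax
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return None
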