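"""Surface-area enlargement factors and environmental utilities.

Per-habitat abundances are reported both per m2 of 3-D substrate surface and
per m2 of seafloor; the conversion is the *enlargement factor* (EF), the
ratio of true substrate surface (plus the planar frame) to the planar frame
area.  Three substrate types need three measurement models:

* algal mats: wet-weight calibrated image analysis of flattened thalli
  (two-sided area), scaled from subsample to main sample;
* seagrass: geometric model, cylindrical rhizomes (lateral surface) plus
  rectangular two-sided leaves, scaled by shoot density;
* bare rock: ball-chain tracing of frame edges and diagonals, quadrilateral
  split into two triangles per diagonal, Heron's formula, mean over the two
  diagonals.

Also here: the clod-card dissolution rate (g/day, a relative water-movement
index) and calendar-day summaries of logger time series.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from math import pi, sqrt

import numpy as np
import pandas as pd

logger = logging.getLogger("habdiv")

BALL_PITCH_M = 0.0024  # centre-to-centre pitch of one chain ball, metres


@dataclass
class AlgalSurfaceSample:
    """Wet weights and subsample area for the mat-surface calibration."""

    ww_subsample: float   # g
    sa_subsample: float   # m2, two-sided
    ww_main: float        # g
    frame_area: float = 0.09  # m2

    def __post_init__(self) -> None:
        if min(self.ww_subsample, self.sa_subsample, self.ww_main, self.frame_area) <= 0:
            raise ValueError("weights and areas must be positive")


@dataclass
class SeagrassGeometry:
    """Shoot geometry and density for the seagrass surface model."""

    rhizome_radius: float      # m
    rhizome_length: float      # m
    leaf_length: float         # m
    leaf_width: float          # m
    leaves_per_rhizome: float
    rhizomes_per_m2: float
    frame_area: float = 0.16   # m2

    def __post_init__(self) -> None:
        dims = (self.rhizome_radius, self.rhizome_length, self.leaf_length,
                self.leaf_width)
        if min(dims) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if self.leaves_per_rhizome < 0 or self.rhizomes_per_m2 < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ChainFrame:
    """Ball-chain lengths (m) traced over a 0.20 x 0.20 m frame.

    ``edges`` in frame order (e1..e4), ``diagonals`` = (corner1-corner3,
    corner2-corner4).  Use :meth:`from_link_counts` for raw link counts.
    """

    edges: tuple[float, float, float, float]
    diagonals: tuple[float, float]
    frame_side: float = 0.20

    @classmethod
    def from_link_counts(cls, edge_links, diagonal_links, frame_side: float = 0.20):
        to_m = lambda n: round(n) * BALL_PITCH_M  # partial links round to whole
        return cls(
            edges=tuple(to_m(n) for n in edge_links),
            diagonals=tuple(to_m(n) for n in diagonal_links),
            frame_side=frame_side,
        )

    @property
    def frame_area(self) -> float:
        return self.frame_side ** 2


def heron_area(a: float, b: float, c: float) -> float:
    """Triangle area from three side lengths (Heron's formula)."""
    if a + b <= c or b + c <= a or a + c <= b:
        raise ValueError(f"triangle inequality violated for sides ({a}, {b}, {c})")
    s = (a + b + c) / 2.0
    return sqrt(s * (s - a) * (s - b) * (s - c))


def ef_phyllophora(s: AlgalSurfaceSample) -> float:
    """Mat enlargement factor from the wet-weight calibrated thallus area.

    SA_MS = WW_MS * SA_SS / WW_SS;  EF = (SA_MS + frame) / frame.
    """
    sa_main = s.ww_main * s.sa_subsample / s.ww_subsample
    return (sa_main + s.frame_area) / s.frame_area


def ef_posidonia(g: SeagrassGeometry, include: str = "holobiont") -> float:
    """Seagrass enlargement factor from shoot geometry and density.

    Per shoot: lateral cylinder surface 2*pi*r*h for the rhizome and
    two-sided rectangles 2*L*W per leaf.  EF = SA_shoot * density + 1
    (equivalently (SA_in_frame + frame) / frame).  ``include`` selects the
    holobiont, leaves-only or rhizomes-only variant.
    """
    sa_rhizome = 2.0 * pi * g.rhizome_radius * g.rhizome_length
    sa_leaves = 2.0 * g.leaf_length * g.leaf_width * g.leaves_per_rhizome
    if include == "holobiont":
        sa_shoot = sa_rhizome + sa_leaves
    elif include == "leaves":
        sa_shoot = sa_leaves
    elif include == "rhizomes":
        sa_shoot = sa_rhizome
    else:
        raise ValueError(f"unknown include {include!r}")
    return sa_shoot * g.rhizomes_per_m2 + 1.0


def ef_hardbottom(c: ChainFrame) -> float:
    """Rock enlargement factor from chain-traced quadrilateral surfaces.

    Each diagonal splits the traced quadrilateral into two Heron triangles;
    the two diagonal-based total areas are averaged and divided by the
    planar frame area.  Flat substrate gives EF = 1 exactly.
    """
    e1, e2, e3, e4 = c.edges
    d1, d2 = c.diagonals
    area1 = heron_area(e1, e2, d1) + heron_area(e3, e4, d1)
    area2 = heron_area(e2, e3, d2) + heron_area(e4, e1, d2)
    return ((area1 + area2) / 2.0) / c.frame_area


def clod_card_rate(w_pre: float, w_post: float, days: float) -> float:
    """Gypsum dissolution rate in g/day (relative water-movement index)."""
    if days <= 0:
        raise ValueError("deployment duration must be positive")
    if w_post > w_pre:
        raise ValueError("clod card gained weight: contamination suspected")
    return (w_pre - w_post) / days


def daily_summary(series: pd.Series) -> pd.DataFrame:
    """Calendar-day mean/min/max of a timestamped logger series.

    Days without data are omitted (and logged); timestamps must be
    monotone non-decreasing.
    """
    if series.empty:
        raise ValueError("empty series")
    idx = pd.DatetimeIndex(series.index)
    if not idx.is_monotonic_increasing:
        raise ValueError("timestamps must be monotone non-decreasing")
    grouped = series.groupby(idx.normalize()).agg(["mean", "min", "max", "count"])
    full = pd.date_range(grouped.index.min(), grouped.index.max(), freq="D")
    missing = full.difference(grouped.index)
    if len(missing):
        logger.warning("daily_summary: %d day(s) without data omitted", len(missing))
    return grouped
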