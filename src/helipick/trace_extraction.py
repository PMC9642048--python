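"""Start-end filament coordinate extraction from particle-scorer score maps.

A sliding-window particle scorer produces an image of per-pixel
figure-of-merit (FOM) scores on a down-sampled micrograph.  For filamentous
specimens, individually scored positions are less useful than the lines the
filaments lie on; this module turns the score image into start-end coordinate
pairs of straight filament segments in four steps:

1. binarize the score image at a user-chosen threshold;
2. skeletonize the binary mask to one-pixel-wide medial lines;
3. detect straight line segments on the skeleton with a probabilistic Hough
   transform;
4. merge near-collinear, nearby segments into longer lines.

Steps 1-3 use standard image-processing primitives (scikit-image); step 4 is
the custom merging rule: two segments merge when the angle between them is
below ``merge_angle_deg`` and at least two of their four endpoints each lie
within ``merge_dist`` of the other segment's supporting line.  The merged
start-end pairs, rescaled to original-micrograph pixels, feed straight into
helical segment extraction with orientational priors.

Coordinates are 0-based pixel-centre throughout; x is the column index and
y the row index (y increases downward).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage.morphology import skeletonize as _skimage_skeletonize
from skimage.transform import probabilistic_hough_line

from .helix_geometry import FilamentTrace

__all__ = [
    "ScoreMap",
    "PickerParams",
    "LineSegment",
    "binarize",
    "skeletonize",
    "detect_lines",
    "merge_lines",
    "extract_traces",
    "rescale_to_micrograph",
]


@dataclass(frozen=True)
class ScoreMap:
    """Per-pixel figure-of-merit scores on a down-sampled micrograph.

    ``downsample_factor`` is the number of original micrograph pixels per
    score-map pixel; ``pixel_size_A`` is Angstrom per *original* micrograph
    pixel, so one score-map pixel covers
    ``downsample_factor * pixel_size_A`` Angstrom.
    """

    values: np.ndarray
    downsample_factor: int = 1
    pixel_size_A: float = 1.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] < 1 or values.shape[1] < 1:
            raise ValueError(f"score map must be a 2-D grid, got shape {values.shape}")
        if int(self.downsample_factor) < 1:
            raise ValueError(
                f"downsample_factor must be >= 1, got {self.downsample_factor}"
            )
        if self.pixel_size_A <= 0:
            raise ValueError(f"pixel_size_A must be positive, got {self.pixel_size_A}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "downsample_factor", int(self.downsample_factor))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class PickerParams:
    """Parameters of the four-step extraction.

    ``threshold_t`` is the binarization threshold on the scorer's
    figure-of-merit (for neural-network scorers useful values are typically
    negative logits, e.g. -4 to -7).  ``radius_r`` is half the filament
    width in down-sampled pixels and anchors the derived defaults:

    - minimum Hough line length ``line_length_fl`` = 2 * radius_r,
    - Hough accumulator threshold = round(0.1 * line_length_fl), floored at 1,
    - Hough line gap = radius_r,
    - merge distance = radius_r,
    - merge angle = 10 degrees.

    Use :meth:`derive` to fill the derived fields from threshold and radius.
    """

    threshold_t: float
    radius_r: int
    line_length_fl: int
    hough_threshold: int
    line_gap: int
    merge_angle_deg: float = 10.0
    merge_dist: float = 0.0
    rng_seed: int = 0

    @classmethod
    def derive(
        cls,
        threshold_t: float,
        radius_r: int,
        line_length_fl: Optional[int] = None,
        merge_angle_deg: float = 10.0,
        rng_seed: int = 0,
    ) -> "PickerParams":
        """Build params from threshold and radius using the default rules."""
        if radius_r < 1:
            raise ValueError(f"radius_r must be >= 1, got {radius_r}")
        fl = 2 * radius_r if line_length_fl is None else int(line_length_fl)
        if fl < 1:
            raise ValueError(f"line_length_fl must be >= 1, got {fl}")
        return cls(
            threshold_t=threshold_t,
            radius_r=int(radius_r),
            line_length_fl=fl,
            hough_threshold=max(1, round(0.1 * fl)),
            line_gap=int(radius_r),
            merge_angle_deg=merge_angle_deg,
            merge_dist=float(radius_r),
            rng_seed=rng_seed,
        )

    def __post_init__(self):
        if self.radius_r < 1 or self.line_length_fl < 1:
            raise ValueError("radius_r and line_length_fl must be >= 1")
        if self.hough_threshold < 1 or self.line_gap < 1:
            raise ValueError("hough_threshold and line_gap must be >= 1")
        if not (0.0 < self.merge_angle_deg < 90.0):
            raise ValueError(
                f"merge_angle_deg must be in (0, 90), got {self.merge_angle_deg}"
            )
        if self.merge_dist <= 0:
            object.__setattr__(self, "merge_dist", float(self.radius_r))


class LineSegment:
    """A straight segment between two endpoints in pixel coordinates.

    Geometrically undirected: angle and distance predicates do not depend on
    which endpoint is the start.  Segments produced by merging remember the
    endpoints of their original constituents so that the merged geometry is
    a function of the merged *set*, independent of merge order.
    """

    __slots__ = ("x1", "y1", "x2", "y2", "_members")

    def __init__(self, x1: float, y1: float, x2: float, y2: float,
                 _members: Optional[Tuple[Tuple[float, float, float, float], ...]] = None):
        self.x1 = float(x1)
        self.y1 = float(y1)
        self.x2 = float(x2)
        self.y2 = float(y2)
        # original constituent segments as (x1, y1, x2, y2) tuples
        self._members = _members if _members is not None else (
            (self.x1, self.y1, self.x2, self.y2),
        )

    @property
    def length(self) -> float:
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)

    @property
    def angle_deg(self) -> float:
        """Axial direction in degrees in [-90, 90)."""
        a = math.degrees(math.atan2(self.y2 - self.y1, self.x2 - self.x1))
        if a >= 90.0:
            a -= 180.0
        elif a < -90.0:
            a += 180.0
        return a

    def endpoints(self) -> Tuple[Tuple[float, float], Tuple[float, float]]:
        return (self.x1, self.y1), (self.x2, self.y2)

    def angle_to(self, other: "LineSegment") -> float:
        """Undirected angle between the two segments' axes, in [0, 90]."""
        d = abs(self.angle_deg - other.angle_deg) % 180.0
        return min(d, 180.0 - d)

    def line_distance(self, point: Tuple[float, float]) -> float:
        """Perpendicular distance from a point to this segment's infinite
        supporting line."""
        px, py = point
        dx = self.x2 - self.x1
        dy = self.y2 - self.y1
        norm = math.hypot(dx, dy)
        if norm == 0.0:
            return math.hypot(px - self.x1, py - self.y1)
        return abs(dy * (px - self.x1) - dx * (py - self.y1)) / norm

    def __repr__(self) -> str:
        return (f"LineSegment(({self.x1:.2f}, {self.y1:.2f}) -> "
                f"({self.x2:.2f}, {self.y2:.2f}))")

    def __eq__(self, other) -> bool:
        if not isinstance(other, LineSegment):
            return NotImplemented
        a = (self.x1, self.y1, self.x2, self.y2)
        b = (other.x1, other.y1, other.x2, other.y2)
        return a == b or a == (b[2], b[3], b[0], b[1])

    def __hash__(self):
        return hash(frozenset(((self.x1, self.y1), (self.x2, self.y2))))


def binarize(score_map: ScoreMap, threshold_t: float) -> np.ndarray:
    """Step 1: boolean mask of pixels whose score strictly exceeds the
    threshold.  An all-false mask is a legal output."""
    return score_map.values > threshold_t


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Step 2: one-pixel-wide, 8-connected medial-axis thinning of the mask.

    The skeleton is a subset of the mask, preserves the connectivity of each
    foreground component, and is a fixed point of re-thinning.
    """
    mask = np.asarray(mask, dtype=bool)
    return _skimage_skeletonize(mask)


def detect_lines(skeleton: np.ndarray, params: PickerParams) -> List[LineSegment]:
    """Step 3: probabilistic Hough transform on the skeleton.

    Returns segments at least ``line_length_fl`` pixels long, bridging gaps
    up to ``line_gap`` pixels, with the accumulator threshold
    ``hough_threshold``.  The angle accumulator is sampled at 1-degree steps
    over [-90, 90); candidate pixels are visited in a pseudo-random order
    fixed by ``rng_seed``, making the output deterministic for a given seed.
    Zero-length degenerate segments are dropped.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    theta = np.deg2rad(np.arange(-90.0, 90.0, 1.0))
    raw = probabilistic_hough_line(
        skeleton,
        threshold=params.hough_threshold,
        line_length=params.line_length_fl,
        line_gap=params.line_gap,
        theta=theta,
        rng=params.rng_seed,
    )
    segments = []
    for (x1, y1), (x2, y2) in raw:
        seg = LineSegment(x1, y1, x2, y2)
        if seg.length > 0.0:
            segments.append(seg)
    return segments


def _mergeable(a: LineSegment, b: LineSegment, merge_angle_deg: float,
               merge_dist: float) -> bool:
    """The merge criterion: mutual angle below ``merge_angle_deg`` and at
    least two of the pair's four endpoints each within ``merge_dist`` of the
    *other* segment's infinite supporting line."""
    if a.angle_to(b) >= merge_angle_deg:
        return False
    close = 0
    for p in a.endpoints():
        if b.line_distance(p) < merge_dist:
            close += 1
    for p in b.endpoints():
        if a.line_distance(p) < merge_dist:
            close += 1
    return close >= 2


def _merge_pair(a: LineSegment, b: LineSegment) -> LineSegment:
    """Construct the merged segment from the union of original constituents.

    The merged axis is the length-weighted principal axis (total
    least-squares line) of the constituent segments' endpoints; all
    endpoints are projected onto that axis through their weighted centroid
    and the two extremal projections become the new endpoints.  Fitting
    endpoint positions rather than averaging segment directions keeps a
    short, slightly tilted fragment from rotating the axis of a long merged
    line.  Because the construction uses only the set of original
    constituents, the result does not depend on the order in which pairs
    were merged.
    """
    members = tuple(sorted(set(a._members) | set(b._members)))
    cx = cy = wsum = 0.0
    for (x1, y1, x2, y2) in members:
        w = math.hypot(x2 - x1, y2 - y1)
        if w == 0.0:
            continue
        cx += w * 0.5 * (x1 + x2)
        cy += w * 0.5 * (y1 + y2)
        wsum += w
    cx /= wsum
    cy /= wsum
    # 2x2 weighted scatter of endpoints about the centroid
    sxx = sxy = syy = 0.0
    for (x1, y1, x2, y2) in members:
        w = 0.5 * math.hypot(x2 - x1, y2 - y1)
        if w == 0.0:
            continue
        for px, py in ((x1, y1), (x2, y2)):
            dx, dy = px - cx, py - cy
            sxx += w * dx * dx
            sxy += w * dx * dy
            syy += w * dy * dy
    # principal axis of [[sxx, sxy], [sxy, syy]]
    axis = 0.5 * math.atan2(2.0 * sxy, sxx - syy)
    ux, uy = math.cos(axis), math.sin(axis)

    tmin = math.inf
    tmax = -math.inf
    for (x1, y1, x2, y2) in members:
        for px, py in ((x1, y1), (x2, y2)):
            t = (px - cx) * ux + (py - cy) * uy
            tmin = min(tmin, t)
            tmax = max(tmax, t)
    return LineSegment(
        cx + tmin * ux, cy + tmin * uy, cx + tmax * ux, cy + tmax * uy,
        _members=members,
    )


def merge_lines(
    segments: Sequence[LineSegment],
    merge_angle_deg: float = 10.0,
    merge_dist: float = 5.0,
) -> List[LineSegment]:
    """Step 4: iteratively merge near-collinear, nearby segments.

    Repeatedly scans segment pairs in index order and merges the first pair
    satisfying the criterion, restarting the scan after every accepted
    merge, until no pair merges (a fixed point: the function is idempotent).
    Merging never increases the segment count.
    """
    if not (0.0 < merge_angle_deg < 90.0):
        raise ValueError(f"merge_angle_deg must be in (0, 90), got {merge_angle_deg}")
    if merge_dist <= 0:
        raise ValueError(f"merge_dist must be positive, got {merge_dist}")

    segs = [s for s in segments if s.length > 0.0]
    merged = True
    while merged:
        merged = False
        n = len(segs)
        for i in range(n):
            for j in range(i + 1, n):
                if _mergeable(segs[i], segs[j], merge_angle_deg, merge_dist):
                    new = _merge_pair(segs[i], segs[j])
                    segs = [s for k, s in enumerate(segs) if k not in (i, j)]
                    segs.append(new)
                    merged = True
                    break
            if merged:
                break
    return segs


def rescale_to_micrograph(value: float, downsample_factor: int) -> float:
    """Map a down-sampled pixel-centre coordinate to original-micrograph
    pixel-centre coordinates: ``x_mic = (x_ds + 0.5) * f - 0.5``.

    This is the centre-preserving convention under block down-sampling by
    factor ``f`` (the centre of down-sampled pixel 0 sits at the centre of
    the block of original pixels 0..f-1).
    """
    return (value + 0.5) * downsample_factor - 0.5


def extract_traces(score_map: ScoreMap, params: PickerParams) -> List[FilamentTrace]:
    """Run the full four-step extraction and rescale to micrograph pixels.

    Returns filament traces with consecutive tube identifiers starting at 1,
    in original-micrograph pixel coordinates.
    """
    mask = binarize(score_map, params.threshold_t)
    skel = skeletonize(mask)
    segments = detect_lines(skel, params)
    merged = merge_lines(segments, params.merge_angle_deg, params.merge_dist)

    f = score_map.downsample_factor
    traces = []
    for i, seg in enumerate(merged, start=1):
        traces.append(
            FilamentTrace(
                x_start=rescale_to_micrograph(seg.x1, f),
                y_start=rescale_to_micrograph(seg.y1, f),
                x_end=rescale_to_micrograph(seg.x2, f),
                y_end=rescale_to_micrograph(seg.y2, f),
                tube_id=i,
            )
        )
    return traces
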