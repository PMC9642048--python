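"""Synthetic amyloid micrographs with ground truth, and a surrogate scorer.

The simulator renders dark filaments on a flat background so the picking
pipeline can be exercised end-to-end with a known answer, without a trained
neural-network scorer.  Each filament is a smooth, gently curved centreline
rendered as a ridge with a Gaussian cross-profile whose full-width (FWHM)
varies along the arc.  Three phenotypes mirror what micrograph inspection
distinguishes in real data:

``good``
    Twisted filaments.  The apparent width alternates sinusoidally between
    ``width_min_A`` and ``width_max_A`` with arc period ``crossover_A / 2``
    (a 2-fold projected ribbon repeats its apparent width twice per full
    crossover).  Projected depth follows a thickness-conservation law,
    ``depth = contrast * width_min_A / w(s)``: the narrow projections are
    dark and the wide crossover regions pale, reproducing the alternating
    strong/weak signal of anisotropic cross-sections.

``swollen``
    Damaged, "blobby" filaments: the width is a smooth random field with a
    blob-scale correlation length whose swellings carry it well beyond the
    healthy range, under the same depth law, so both width and contrast
    fluctuate irregularly.

``ribbon``
    Non-twisting flat ribbons: constant apparent width (``width_min_A`` is
    forced equal to ``width_max_A``) and uniformly pale, because a flat
    ribbon lying in the ice always presents its thin dimension to the beam
    (rendered at ``RIBBON_THIN_FACTOR`` times the nominal contrast).

Additive Gaussian pixel noise of standard deviation ``noise_sigma`` is
applied last.  Everything is drawn from one ``rng_seed``; the output is
bit-reproducible.

The surrogate scorer block-averages the micrograph and applies a bank of
oriented anisotropic ridge filters (matched to the filament width across
the axis, elongated along it), takes the strongest response over
orientations, and expresses scores in units of the image's pixel noise.
It stands in for the sliding-window network scorer only; its score scale
is its own, and tests of the extraction pipeline depend on no trained
weights.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.ndimage import rotate as ndi_rotate

from .helix_geometry import FilamentTrace
from .star_io import MicrographImage
from .trace_extraction import ScoreMap

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "PickMetrics",
    "simulate_micrograph",
    "surrogate_score_map",
    "evaluate_picks",
    "RIBBON_THIN_FACTOR",
]

#: Depth factor for non-twisting flat ribbons.  A flat ribbon lying in the
#: ice always presents its thin dimension to the beam: it is a sheet of
#: laterally packed cross-beta protofilaments roughly 20 A thick against
#: ~140 A width, so its projected depth is a small fraction of a twisted
#: filament's narrowest (thickest-in-projection) sections — which is why
#: such data sets are reported to defeat picking unless the threshold is
#: dropped into the noise.
RIBBON_THIN_FACTOR = 0.15

#: FWHM -> Gaussian sigma.
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Correlation length (Angstrom) of the swollen phenotype's width field.
_SWOLLEN_BLOB_A = 150.0

PHENOTYPES = ("good", "swollen", "ribbon")


@dataclass
class SimulationSpec:
    """Parameters of one simulated micrograph.

    Defaults describe a typical recombinant-tau-like field of view: 1024 x
    1024 pixels at 2 A/px (2048 A across), five filaments of 70-140 A
    apparent width with a 720 A crossover, gentle curvature, and unit
    filament contrast.
    """

    image_shape: Tuple[int, int] = (1024, 1024)
    pixel_size_A: float = 2.0
    n_filaments: int = 5
    width_max_A: float = 140.0
    width_min_A: float = 70.0
    crossover_A: float = 720.0
    curvature_max: float = 0.01  # radians of heading change per 100 A of arc
    contrast: float = 1.0
    noise_sigma: float = 0.0
    phenotype: str = "good"
    allow_crossings: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}"
            )
        if self.phenotype == "ribbon":
            # non-twisting: no width modulation
            self.width_min_A = self.width_max_A
        if self.width_min_A > self.width_max_A:
            raise ValueError("width_min_A must not exceed width_max_A")
        if min(self.image_shape) < 1:
            raise ValueError(f"bad image shape {self.image_shape}")
        if self.pixel_size_A <= 0 or self.width_min_A <= 0 or self.crossover_A <= 0:
            raise ValueError("lengths must be positive")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.n_filaments < 0:
            raise ValueError(f"n_filaments must be >= 0, got {self.n_filaments}")
        if self.curvature_max < 0:
            raise ValueError(f"curvature_max must be >= 0, got {self.curvature_max}")


@dataclass
class GroundTruth:
    """True centrelines of the simulated filaments.

    ``polylines[i]`` is an (N, 2) array of (x, y) micrograph-pixel points
    along filament ``filament_ids[i]``, clipped to the image bounds;
    ``params[i]`` records the per-filament draws (phase, curvature, ...).
    """

    polylines: List[np.ndarray]
    filament_ids: List[int]
    params: List[Dict[str, float]]
    pixel_size_A: float
    image_shape: Tuple[int, int]

    def arc_lengths_px(self) -> List[float]:
        return [
            float(np.sum(np.hypot(*np.diff(p, axis=0).T))) for p in self.polylines
        ]

    @property
    def total_length_px(self) -> float:
        return float(sum(self.arc_lengths_px()))


def _width_profile(spec: SimulationSpec, s_A: np.ndarray, rng) -> Tuple[np.ndarray, Dict]:
    """Apparent full-width (A) at arc positions s_A, plus the draws used."""
    mean = 0.5 * (spec.width_min_A + spec.width_max_A)
    amp = 0.5 * (spec.width_max_A - spec.width_min_A)
    if spec.phenotype == "good":
        phase = rng.uniform(0.0, 2.0 * math.pi)
        period = spec.crossover_A / 2.0
        w = mean + amp * np.cos(2.0 * math.pi * s_A / period + phase)
        return w, {"phase": phase}
    if spec.phenotype == "swollen":
        # blob-scale correlated random width field; swelling carries the
        # apparent width well beyond the healthy range, and the depth law
        # then renders the swollen stretches pale and blobby
        step_A = float(s_A[1] - s_A[0]) if len(s_A) > 1 else 1.0
        raw = rng.standard_normal(len(s_A))
        sig = max(1.0, _SWOLLEN_BLOB_A / step_A)
        smooth = gaussian_filter1d(raw, sig, mode="nearest")
        rms = float(np.sqrt(np.mean(smooth**2))) or 1.0
        z = smooth / rms
        w = mean * np.exp(0.55 * z)
        w = np.clip(w, 0.5 * spec.width_min_A, 2.5 * spec.width_max_A)
        return w, {"blob_A": _SWOLLEN_BLOB_A}
    # ribbon: constant
    return np.full(len(s_A), spec.width_max_A), {}


def _depth_profile(spec: SimulationSpec, w_A: np.ndarray) -> np.ndarray:
    """Projected depth below background at each arc sample.

    Thickness conservation for an anisotropic cross-section: the product of
    apparent width and beam-path thickness is roughly constant, so depth
    scales as 1/w, normalised to ``contrast`` at the narrowest projection.
    Flat ribbons always present their thin dimension and are uniformly pale.
    """
    if spec.phenotype == "ribbon":
        return np.full(len(w_A), RIBBON_THIN_FACTOR * spec.contrast)
    return spec.contrast * spec.width_min_A / w_A


def _trace_centreline(spec: SimulationSpec, rng) -> Tuple[np.ndarray, Dict]:
    """One smooth centreline crossing the image, with bounded curvature.

    The filament is a constant-curvature arc (curvature drawn uniformly
    within +-curvature_max) through a random anchor point at a random
    heading, marched in both directions until it leaves the image.
    """
    h, w = spec.image_shape
    step_px = 2.0
    step_A = step_px * spec.pixel_size_A
    kappa = rng.uniform(-spec.curvature_max, spec.curvature_max)  # rad / 100 A
    dtheta = kappa * step_A / 100.0
    # anchors spread over the field of view, as in a real micrograph
    x0 = rng.uniform(0.05 * w, 0.95 * w)
    y0 = rng.uniform(0.05 * h, 0.95 * h)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    # filaments have finite length (fragmented during sample preparation);
    # a few crossover distances is typical
    length_A = rng.uniform(2.0, 4.5) * spec.crossover_A
    half_steps = max(2, int(0.5 * length_A / step_A))

    def march(sign: float) -> List[Tuple[float, float]]:
        pts = []
        x, y, th = x0, y0, theta0
        for _ in range(half_steps):
            x += sign * step_px * math.cos(th)
            y += sign * step_px * math.sin(th)
            th += sign * dtheta
            if not (0.0 <= x <= w - 1.0 and 0.0 <= y <= h - 1.0):
                break
            pts.append((x, y))
        return pts

    back = march(-1.0)[::-1]
    fwd = march(+1.0)
    pts = back + [(x0, y0)] + fwd
    clipped = len(pts) < 2 * half_steps + 1  # hit the image border
    return np.asarray(pts, dtype=np.float64), {
        "curvature": kappa,
        "heading": theta0,
        "x0": x0,
        "y0": y0,
        "length_A": length_A,
        "clipped": float(clipped),
    }


def _render_filament(ridge: np.ndarray, poly: np.ndarray, w_A: np.ndarray,
                     depth: np.ndarray, pixel_A: float) -> None:
    """Max-combine Gaussian cross-profile stamps along a centreline.

    Max-combining (rather than summing) keeps the ridge depth equal to the
    local ``depth`` regardless of how densely the arc is sampled.
    """
    h, w = ridge.shape
    sigma_px = (w_A / pixel_A) / _FWHM
    # resample the centreline so consecutive stamps are <= 0.5 sigma apart
    seg = np.hypot(*np.diff(poly, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    min_sig = max(0.5, float(np.min(sigma_px)))
    t = np.arange(0.0, s[-1], 0.5 * min_sig) if s[-1] > 0 else np.array([0.0])
    xs = np.interp(t, s, poly[:, 0])
    ys = np.interp(t, s, poly[:, 1])
    sig = np.interp(t, s, sigma_px)
    dep = np.interp(t, s, depth)

    for x, y, sg, dp in zip(xs, ys, sig, dep):
        r = int(math.ceil(3.0 * sg))
        xi, yi = int(round(x)), int(round(y))
        x_lo, x_hi = max(0, xi - r), min(w, xi + r + 1)
        y_lo, y_hi = max(0, yi - r), min(h, yi + r + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        gx = np.arange(x_lo, x_hi, dtype=np.float64) - x
        gy = np.arange(y_lo, y_hi, dtype=np.float64) - y
        d2 = gy[:, None] ** 2 + gx[None, :] ** 2
        stamp = dp * np.exp(-d2 / (2.0 * sg * sg))
        patch = ridge[y_lo:y_hi, x_lo:x_hi]
        np.maximum(patch, stamp, out=patch)


def _overlap_fraction(poly: np.ndarray, others: List[np.ndarray],
                      min_sep_px: float) -> float:
    """Fraction of a candidate centreline lying within min_sep_px of any
    existing centreline."""
    if not others:
        return 0.0
    pts = poly[:: max(1, len(poly) // 100)]
    close = np.zeros(len(pts), dtype=bool)
    for other in others:
        d, _ = _polyline_dist_and_dir(pts, other)
        close |= d < min_sep_px
    return float(close.mean())


def simulate_micrograph(spec: SimulationSpec) -> Tuple[MicrographImage, GroundTruth]:
    """Render one micrograph and its ground-truth centrelines.

    Filaments are dark (negative) on a zero background, matching cryo-EM
    contrast conventions; additive Gaussian noise is applied last.
    Bit-reproducible for a fixed ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_shape
    ridge = np.zeros((h, w), dtype=np.float64)

    polylines, ids, params = [], [], []
    for i in range(spec.n_filaments):
        # steric exclusion: filaments in a thin ice layer cannot lie on top
        # of each other, so reject candidates that run along an existing
        # filament; with allow_crossings=False (clean fixture geometry)
        # reject any contact at all
        if spec.allow_crossings:
            min_sep_px = spec.width_max_A / spec.pixel_size_A
            max_overlap = 0.15
        else:
            min_sep_px = 2.0 * spec.width_max_A / spec.pixel_size_A
            max_overlap = 0.0
        poly, draws = _trace_centreline(spec, rng)
        for _ in range(80):
            interior_ok = spec.allow_crossings or not draws["clipped"]
            if (len(poly) >= 2 and interior_ok
                    and _overlap_fraction(poly, polylines, min_sep_px) <= max_overlap):
                break
            poly, draws = _trace_centreline(spec, rng)
        if len(poly) < 2:
            continue
        seg = np.hypot(*np.diff(poly, axis=0).T)
        s_A = np.concatenate([[0.0], np.cumsum(seg)]) * spec.pixel_size_A
        w_A, wdraws = _width_profile(spec, s_A, rng)
        depth = _depth_profile(spec, w_A)
        _render_filament(ridge, poly, w_A, depth, spec.pixel_size_A)
        polylines.append(poly)
        ids.append(i + 1)
        params.append({**draws, **wdraws})

    image = -ridge
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)

    mic = MicrographImage(
        values=image, pixel_size_A=spec.pixel_size_A,
        source_name=f"synthetic_{spec.phenotype}_{spec.rng_seed:05d}",
    )
    truth = GroundTruth(
        polylines=polylines, filament_ids=ids, params=params,
        pixel_size_A=spec.pixel_size_A, image_shape=spec.image_shape,
    )
    return mic, truth


def surrogate_score_map(
    image: MicrographImage,
    width_A: float,
    downsample_factor: int = 4,
    n_orientations: int = 36,
    elongation: float = 1.75,
) -> ScoreMap:
    """Oriented matched-filter figure-of-merit map for dark ridges.

    Block-averages the micrograph by ``downsample_factor``, then applies a
    bank of anisotropic Gaussian ridge filters: at each of
    ``n_orientations`` directions the image is convolved with a Gaussian of
    FWHM ``width_A`` across the ridge (minus a 3x wider Gaussian as the
    local background estimate) and ``elongation`` times longer along it.
    Integrating along the axis is what lets the filter carry the weak, wide
    crossover sections of a twisted filament, much as a sliding-window
    classifier integrates context.  The strongest (darkest) response over
    all orientations is sign-flipped, so filaments score high, and
    standardised to zero mean and unit variance.

    A width below one down-sampled pixel is clamped (with a warning); a
    constant image yields an all-zero map.
    """
    if width_A <= 0:
        raise ValueError(f"width_A must be positive, got {width_A}")
    f = int(downsample_factor)
    if f < 1:
        raise ValueError(f"downsample_factor must be >= 1, got {downsample_factor}")

    values = image.values
    h, w = values.shape
    hc, wc = (h // f) * f, (w // f) * f
    ds = values[:hc, :wc].reshape(hc // f, f, wc // f, f).mean(axis=(1, 3))

    ds_pixel_A = image.pixel_size_A * f
    if width_A < ds_pixel_A:
        warnings.warn(
            f"filament width {width_A} A below one down-sampled pixel "
            f"({ds_pixel_A} A); clamping", stacklevel=2,
        )
        width_A = ds_pixel_A
    sigma_across = (width_A / ds_pixel_A) / _FWHM
    sigma_along = elongation * sigma_across

    # pad with the background median before rotating: otherwise edge-padding
    # streaks and rotation corner loss masquerade as strong edge ridges
    pad = int(math.ceil(3.0 * sigma_along)) + max(ds.shape) // 4
    median = float(np.median(ds))
    padded = np.pad(ds, pad, mode="constant", constant_values=median)

    darkest = None
    for theta in np.arange(0.0, 180.0, 180.0 / n_orientations):
        rot = ndi_rotate(padded, theta, reshape=False, order=1,
                         mode="constant", cval=median)
        resp = gaussian_filter(rot, (sigma_along, sigma_across), mode="nearest") \
            - gaussian_filter(rot, (sigma_along, 3.0 * sigma_across), mode="nearest")
        back = ndi_rotate(resp, -theta, reshape=False, order=1,
                          mode="nearest")[pad:-pad, pad:-pad]
        darkest = back if darkest is None else np.minimum(darkest, back)

    score = -darkest - float(np.median(-darkest))
    # fixed, content-independent score scale: the pixel noise of the
    # down-sampled image, estimated from first differences (filament
    # structure is smooth at the one-pixel scale and cancels).  A field of
    # weak objects must not be rescaled up to look like a field of strong
    # ones, so image-content statistics are deliberately avoided.
    diffs = np.diff(ds, axis=1)
    noise = 1.4826 * float(np.median(np.abs(diffs - np.median(diffs)))) / math.sqrt(2.0)
    # floor the scale at half of the peak response: in (nearly) noiseless
    # images the difference estimator only sees the filaments' own smooth
    # tails, which would blow the scores up arbitrarily
    scale = max(noise, float(score.max()) / 2.0)
    if scale <= 0.0:
        score = np.zeros_like(score)
    else:
        score = score / scale
    return ScoreMap(values=score, downsample_factor=f, pixel_size_A=image.pixel_size_A)


# ---------------------------------------------------------------------------
# Pick evaluation against ground truth


@dataclass(frozen=True)
class PickMetrics:
    """Precision of the picked traces, per-filament recall, and the covered
    fraction of true filament length.  All in [0, 1]."""

    precision: float
    recall_by_length: float
    coverage: float
    n_traces: int = 0
    n_true_positive: int = 0


def _point_segment_dist(px, py, x1, y1, x2, y2):
    """Distance from points (px, py) to the finite segment; vectorised."""
    dx, dy = x2 - x1, y2 - y1
    norm2 = dx * dx + dy * dy
    safe = np.where(norm2 == 0.0, 1.0, norm2)
    t = np.clip(((px - x1) * dx + (py - y1) * dy) / safe, 0.0, 1.0)
    t = np.where(norm2 == 0.0, 0.0, t)
    return np.hypot(px - (x1 + t * dx), py - (y1 + t * dy))


def _polyline_dist_and_dir(points: np.ndarray, poly: np.ndarray):
    """Min distance of each point to a polyline + local axial direction (deg)."""
    x1, y1 = poly[:-1, 0], poly[:-1, 1]
    x2, y2 = poly[1:, 0], poly[1:, 1]
    px = points[:, 0][:, None]
    py = points[:, 1][:, None]
    d = _point_segment_dist(px, py, x1[None, :], y1[None, :], x2[None, :], y2[None, :])
    idx = np.argmin(d, axis=1)
    dmin = d[np.arange(len(points)), idx]
    ang = np.degrees(np.arctan2(y2[idx] - y1[idx], x2[idx] - x1[idx]))
    ang = np.where(ang >= 90.0, ang - 180.0, ang)
    ang = np.where(ang < -90.0, ang + 180.0, ang)
    return dmin, ang


def _axial_diff(a_deg: float, b_deg: np.ndarray) -> np.ndarray:
    d = np.abs(a_deg - b_deg) % 180.0
    return np.minimum(d, 180.0 - d)


def evaluate_picks(
    traces: Sequence[FilamentTrace],
    truth: GroundTruth,
    dist_tol_px: float,
    angle_tol_deg: float,
) -> PickMetrics:
    """Score picked traces against ground-truth centrelines.

    A trace is a true positive when both its endpoints lie within
    ``dist_tol_px`` of the same truth polyline and its direction is within
    ``angle_tol_deg`` of the local polyline direction at the nearest points.
    Traces are matched greedily by decreasing length (ties by tube_id).
    Coverage is the fraction of total truth arc length lying within
    ``dist_tol_px`` of a true-positive trace; ``recall_by_length`` is the
    fraction of truth filaments individually covered over at least half
    their length.  With no picked traces, precision is 1 by convention and
    coverage 0.
    """
    if dist_tol_px <= 0 or angle_tol_deg <= 0:
        raise ValueError("tolerances must be positive")
    if not truth.polylines:
        raise ValueError("empty ground truth")

    order = sorted(traces, key=lambda t: (-t.length_px, t.tube_id))
    true_pos: List[FilamentTrace] = []
    for tr in order:
        ends = np.array(
            [[tr.x_start, tr.y_start], [tr.x_end, tr.y_end]], dtype=np.float64
        )
        ang = math.degrees(math.atan2(tr.y_end - tr.y_start, tr.x_end - tr.x_start))
        matched = False
        for poly in truth.polylines:
            dmin, local = _polyline_dist_and_dir(ends, poly)
            if np.all(dmin <= dist_tol_px) and np.all(
                _axial_diff(ang, local) <= angle_tol_deg
            ):
                matched = True
                break
        if matched:
            true_pos.append(tr)

    n_traces = len(traces)
    precision = 1.0 if n_traces == 0 else len(true_pos) / n_traces

    total_len = 0.0
    covered_len = 0.0
    n_filaments_recalled = 0
    for poly in truth.polylines:
        seg_len = np.hypot(*np.diff(poly, axis=0).T)
        mids = 0.5 * (poly[:-1] + poly[1:])
        covered = np.zeros(len(mids), dtype=bool)
        for tr in true_pos:
            d = _point_segment_dist(
                mids[:, 0], mids[:, 1], tr.x_start, tr.y_start, tr.x_end, tr.y_end
            )
            covered |= d <= dist_tol_px
        flen = float(seg_len.sum())
        fcov = float(seg_len[covered].sum())
        total_len += flen
        covered_len += fcov
        if flen > 0 and fcov / flen >= 0.5:
            n_filaments_recalled += 1

    coverage = covered_len / total_len if total_len > 0 else 0.0
    recall = n_filaments_recalled / len(truth.polylines)
    return PickMetrics(
        precision=precision,
        recall_by_length=recall,
        coverage=coverage,
        n_traces=n_traces,
        n_true_positive=len(true_pos),
    )
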