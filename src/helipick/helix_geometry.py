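"""Helical bookkeeping arithmetic for amyloid filament processing.

Amyloid filaments are cross-beta helical polymers with a canonical axial rise
of 4.75 Angstrom per beta-rung.  A twisted filament completes a half-turn over
its crossover distance ``d`` (visible in micrographs as the period of
apparent-width alternation), which fixes the helical twist per rung as
``rise * 180 / d`` degrees.  This module collects that conversion together
with the small pieces of pixel/spacing arithmetic needed when setting up
segment extraction and refinement: inter-particle spacing from the rise and
the number of asymmetric units, down-scaled pixel sizes, the picking radius
in down-sampled pixels, and the pixel-size recalibration implied by an
off-nominal refined rise.

All distances are in Angstrom unless a name says pixels; angles in degrees.
The left-handed twist common to most amyloids is reported with a negative
sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List

#: Canonical axial rise of one beta-rung in a cross-beta amyloid stack (A).
CANONICAL_RISE_A = 4.75


@dataclass(frozen=True)
class HelicalParams:
    """Helical symmetry bookkeeping for one filament type.

    Parameters
    ----------
    rise_A : float
        Axial rise per asymmetric unit in Angstrom (canonically 4.75).
    crossover_A : float
        Crossover distance in Angstrom (arc length of a half-turn).
    n_asu : int
        Number of unique asymmetric units between extracted segments.
    twist_deg : float
        Signed twist per asymmetric unit, negative for left-handed helices.
        Derived from ``crossover_A`` when not given explicitly.
    """

    rise_A: float = CANONICAL_RISE_A
    crossover_A: float = 720.0
    n_asu: int = 3
    twist_deg: float = field(default=0.0)

    def __post_init__(self):
        if self.rise_A <= 0:
            raise ValueError(f"rise_A must be positive, got {self.rise_A}")
        if self.crossover_A <= 0:
            raise ValueError(f"crossover_A must be positive, got {self.crossover_A}")
        if self.n_asu < 1:
            raise ValueError(f"n_asu must be >= 1, got {self.n_asu}")
        if self.twist_deg == 0.0:
            object.__setattr__(
                self, "twist_deg", twist_from_crossover(self.crossover_A, self.rise_A)
            )

    @property
    def interparticle_A(self) -> float:
        return interparticle_distance(self.rise_A, self.n_asu)


@dataclass(frozen=True)
class FilamentTrace:
    """One picked straight filament segment in original-micrograph pixels.

    The start and end points define the line along which individual particle
    images are extracted; curved filaments are represented as multiple
    shorter traces, each with its own ``tube_id``.
    """

    x_start: float
    y_start: float
    x_end: float
    y_end: float
    tube_id: int = 1

    @property
    def length_px(self) -> float:
        return math.hypot(self.x_end - self.x_start, self.y_end - self.y_start)

    @property
    def psi_deg(self) -> float:
        """In-plane angle prior of the trace direction.

        Convention: ``psi = -atan2(dy, dx)`` in degrees, wrapped to
        (-180, 180], with image y increasing downward.  A trace along +x has
        psi 0; one along image-up (-y) has psi 90.
        """
        dx = self.x_end - self.x_start
        dy = self.y_end - self.y_start
        psi = -math.degrees(math.atan2(dy, dx))
        if psi <= -180.0:
            psi += 360.0
        return psi


@dataclass(frozen=True)
class ParticleRecord:
    """One extraction position along a filament trace, with priors.

    ``tilt_prior_deg`` is fixed at 90 because filaments lie in the image
    plane; ``psi_prior_deg`` is the in-plane direction of the trace;
    ``track_length_A`` is the arc distance from the trace start in Angstrom.
    """

    x: float
    y: float
    tube_id: int
    psi_prior_deg: float
    tilt_prior_deg: float = 90.0
    track_length_A: float = 0.0


def twist_from_crossover(crossover_A: float, rise_A: float = CANONICAL_RISE_A) -> float:
    """Helical twist (degrees per asymmetric unit) from a crossover distance.

    A filament turns 180 degrees over one crossover distance ``d``, so the
    twist per rung of rise ``r`` is ``r * 180 / d``.  Returned negative,
    following the left-handed convention of most amyloid filaments
    (e.g. d = 720 A at the canonical rise gives -1.19 deg at two decimals).
    """
    if crossover_A <= 0:
        raise ValueError(f"crossover_A must be positive, got {crossover_A}")
    if rise_A <= 0:
        raise ValueError(f"rise_A must be positive, got {rise_A}")
    return -(rise_A * 180.0) / crossover_A


def crossover_from_twist(twist_deg: float, rise_A: float = CANONICAL_RISE_A) -> float:
    """Inverse of :func:`twist_from_crossover`; sign of the twist is ignored."""
    if twist_deg == 0:
        raise ValueError("twist_deg must be nonzero")
    if rise_A <= 0:
        raise ValueError(f"rise_A must be positive, got {rise_A}")
    return (rise_A * 180.0) / abs(twist_deg)


def interparticle_distance(rise_A: float, n_asu: int) -> float:
    """Spacing between extracted segments: rise times asymmetric units.

    Three beta-rungs at the canonical rise give 14.25 A (reported as 14.2 at
    one decimal under round-half-to-even).
    """
    if rise_A <= 0:
        raise ValueError(f"rise_A must be positive, got {rise_A}")
    if int(n_asu) != n_asu or n_asu < 1:
        raise ValueError(f"n_asu must be an integer >= 1, got {n_asu}")
    return rise_A * int(n_asu)


def downscaled_pixel_size(pixel_A: float, box_px: int, downscaled_box_px: int) -> float:
    """Pixel size after extracting box_px and rescaling to downscaled_box_px.

    E.g. 0.824 A pixels in a 768-pixel box downscaled to 128 pixels give
    4.944 A (4.94 at two decimals).
    """
    if pixel_A <= 0:
        raise ValueError(f"pixel_A must be positive, got {pixel_A}")
    if box_px <= 0 or downscaled_box_px <= 0:
        raise ValueError("box sizes must be positive")
    if downscaled_box_px > box_px:
        raise ValueError(
            f"downscaled box ({downscaled_box_px}) larger than box ({box_px})"
        )
    return pixel_A * box_px / downscaled_box_px


def radius_pixels(diameter_A: float, downscaled_pixel_A: float) -> int:
    """Picking radius in down-sampled pixels: half the particle diameter.

    The diameter should reflect the average filament width; the result is
    rounded to the nearest pixel and floored at 1.
    """
    if diameter_A <= 0:
        raise ValueError(f"diameter_A must be positive, got {diameter_A}")
    if downscaled_pixel_A <= 0:
        raise ValueError(
            f"downscaled_pixel_A must be positive, got {downscaled_pixel_A}"
        )
    return max(1, round(diameter_A / 2.0 / downscaled_pixel_A))


def corrected_pixel_size(
    nominal_pixel_A: float, observed_rise_A: float, expected_rise_A: float = CANONICAL_RISE_A
) -> float:
    """Recalibrated pixel size implied by an off-nominal refined rise.

    Microscope pixel-size calibration errors of a few percent show up as a
    refined helical rise deviating from the expected 4.75 A.  Attributing the
    whole deviation to calibration, the true pixel size is
    ``nominal * expected_rise / observed_rise``.
    """
    if nominal_pixel_A <= 0:
        raise ValueError(f"nominal_pixel_A must be positive, got {nominal_pixel_A}")
    if observed_rise_A <= 0:
        raise ValueError(f"observed_rise_A must be positive, got {observed_rise_A}")
    if expected_rise_A <= 0:
        raise ValueError(f"expected_rise_A must be positive, got {expected_rise_A}")
    return nominal_pixel_A * expected_rise_A / observed_rise_A


def sample_particles(
    trace: FilamentTrace, spacing_A: float, pixel_A: float
) -> List[ParticleRecord]:
    """Place particle records along a trace at a fixed arc spacing.

    Particles sit at arc positions ``i * spacing_A`` for
    ``i = 0 .. floor(L / spacing_A)`` where ``L`` is the trace length in
    Angstrom, so the first particle is at the trace start and none overshoots
    the end.  Every record carries the trace's in-plane angle as its psi
    prior, a tilt prior of 90 degrees, and its arc distance from the start as
    the helical track length.
    """
    if spacing_A <= 0:
        raise ValueError(f"spacing_A must be positive, got {spacing_A}")
    if pixel_A <= 0:
        raise ValueError(f"pixel_A must be positive, got {pixel_A}")
    length_px = trace.length_px
    if length_px <= 0:
        raise ValueError(f"degenerate zero-length trace (tube {trace.tube_id})")

    length_A = length_px * pixel_A
    n = int(math.floor(length_A / spacing_A)) + 1
    ux = (trace.x_end - trace.x_start) / length_px
    uy = (trace.y_end - trace.y_start) / length_px
    psi = trace.psi_deg

    records = []
    for i in range(n):
        s_A = i * spacing_A
        s_px = s_A / pixel_A
        records.append(
            ParticleRecord(
                x=trace.x_start + ux * s_px,
                y=trace.y_start + uy * s_px,
                tube_id=trace.tube_id,
                psi_prior_deg=psi,
                tilt_prior_deg=90.0,
                track_length_A=s_A,
            )
        )
    return records
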