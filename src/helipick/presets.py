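"""Default picking configuration for the synthetic study conditions.

The canonical particle diameter is 120 A — the particle diameter used for
network training on recombinant tau, reflecting the average filament width.
Everything else follows from it via the standard derivation rules: the
radius is half the diameter in down-sampled pixels, the minimum Hough line
length twice the radius, and so on.

The surrogate scorer expresses figure-of-merit values in units of the
down-sampled image's pixel noise; on that scale background fluctuations
stay below ~0.1 and healthy filaments (including their weak, wide crossover
sections) score above ~1, so the default binarization threshold sits at
1.1.  Like any picking threshold it is meant to be tuned per data set
(``--fp`` shows the four diagnostic steps for that purpose).
"""

from __future__ import annotations

from .helix_geometry import radius_pixels
from .trace_extraction import PickerParams

#: Particle diameter in Angstrom used for the default picking radius.
DEFAULT_PARTICLE_DIAMETER_A = 120.0

#: Default binarization threshold on the surrogate scorer's noise-unit scale.
DEFAULT_SCORE_THRESHOLD = 1.1

#: Default block-averaging factor between micrograph and score map.
DEFAULT_DOWNSAMPLE = 4


def default_picker_params(
    pixel_size_A: float,
    downsample_factor: int = DEFAULT_DOWNSAMPLE,
    threshold_t: float = DEFAULT_SCORE_THRESHOLD,
    diameter_A: float = DEFAULT_PARTICLE_DIAMETER_A,
    rng_seed: int = 0,
) -> PickerParams:
    """Picker parameters from the default diameter and threshold.

    ``pixel_size_A`` is the original micrograph pixel size; the radius is
    computed against the down-sampled pixel.
    """
    r = radius_pixels(diameter_A, pixel_size_A * downsample_factor)
    return PickerParams.derive(threshold_t=threshold_t, radius_r=r,
                               rng_seed=rng_seed)
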