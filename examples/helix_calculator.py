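"""Helical bookkeeping: from a measured crossover distance to refinement
settings, extraction spacing, and pixel-size sanity checks.

Run:  python examples/helix_calculator.py
"""

from helipick import (
    corrected_pixel_size,
    downscaled_pixel_size,
    interparticle_distance,
    radius_pixels,
    twist_from_crossover,
)

# A crossover distance of 720 A measured from the micrographs fixes the
# helical twist per 4.75 A beta-rung (negative: left-handed).
twist = twist_from_crossover(720.0, rise_A=4.75)
print(f"crossover 720 A  ->  twist {twist:.4f} deg (use {twist:.2f} in refinement)")

# Extracting one particle every three beta-rungs:
spacing = interparticle_distance(4.75, 3)
print(f"3 asymmetric units -> inter-particle distance {spacing:.2f} A "
      f"(~{round(spacing, 1)})")

# Extraction at box 768 px downscaled to 128 px from 0.824 A pixels:
ds_pixel = downscaled_pixel_size(0.824, 768, 128)
print(f"box 768 -> 128 px at 0.824 A/px -> downscaled pixel {ds_pixel:.3f} A")

# The picking radius is half the particle diameter in down-sampled pixels:
radius = radius_pixels(120.0, ds_pixel)
print(f"particle diameter 120 A -> picking radius {radius} down-sampled px")

# A refined rise of 4.9 A instead of 4.75 A signals pixel-size miscalibration:
pixel = corrected_pixel_size(1.0, observed_rise_A=4.9)
print(f"nominal 1.000 A/px with refined rise 4.90 A -> true pixel "
      f"{pixel:.5f} A")
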