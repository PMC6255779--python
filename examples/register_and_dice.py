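"""Recover a known rigid transform by mask registration.

A spiked nodule mask is rotated by (4, -6, 2) degrees and shifted by a few
voxels, then registered back to the original with the bounded rotation
search plus mid-slice cross-correlation. Dice close to 1 after registration
(against ~0.8 before) shows the transform was recovered.
"""

from pulmoct.phantom import GridSpec, NoduleSpec, generate_spiked_sphere_mask
from pulmoct.registration import _shift_mask, register_to_reference, rotate_mask
from pulmoct.stats import dice_coefficient

grid = GridSpec(shape=(100, 100, 100), spacing_mm=(0.14, 0.14, 0.14))
reference = generate_spiked_sphere_mask(
    NoduleSpec(kind="spiked_sphere", diameter_mm=6.0, center_mm=(7.0, 7.0, 7.0)), grid
)

moved = rotate_mask(reference, (4.0, -6.0, 2.0))
moved = moved.with_values(_shift_mask(moved.values, (3, -2, 1)))
print(f"Dice before registration: {dice_coefficient(moved, reference).value:.3f}")

registered = register_to_reference(moved, reference, search=True)
print(f"Dice after registration:  {dice_coefficient(registered, reference).value:.3f}")
print("The residual below 1.0 is re-binarisation loss from interpolating a "
      "voxelised shape, not a registration error.")
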