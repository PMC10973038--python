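"""Frame-safe rigid-transform algebra: the error chain's foundation.

Builds the kind of transform chain the navigation error computation uses
(image -> matrix -> patient reference) and shows that mischained frames
are refused rather than silently multiplied.
"""

import numpy as np

import navregsim as nv

# two random links of the automatic-registration chain
image_to_matrix = nv.random_rigid(1, max_rotation_deg=20, max_translation_mm=50,
                                  source_frame="intraop_cbct", target_frame="matrix")
matrix_to_ref = nv.random_rigid(2, max_rotation_deg=20, max_translation_mm=50,
                                source_frame="matrix", target_frame="patient_ref")

chain = nv.compose(matrix_to_ref, image_to_matrix)
print(f"chain maps {chain.source_frame} -> {chain.target_frame}")

# a point mapped through the chain and back returns exactly
p = nv.point_set([[12.0, -3.0, 40.0]], "intraop_cbct")
round_trip = nv.apply(nv.invert(chain), nv.apply(chain, p))
print("round-trip error (mm):", np.abs(round_trip.coordinates - p.coordinates).max())
# ~1e-15: composition and inversion are exact to machine precision

# composing out of order is a hard error — the main anti-bug guard
try:
    nv.compose(image_to_matrix, matrix_to_ref)
except nv.FrameMismatchError as exc:
    print("refused mischained composition:", exc)
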