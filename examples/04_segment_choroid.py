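"""Segment the choroid-sclera interface and score it against ground truth.

Flat-preset phantoms have a constant CSI depth, so the graph-search trace
can be scored exactly.  Errors grow as the bit depth falls: the choroidal
signal sits close to the noise floor and is the first casualty of coarse
quantization.
"""

import numpy as np

from octbit import (
    AcquisitionConfig, BoundaryTrace, boundary_error, make_phantom, process,
    quantize_fringe, segment_csi, synthesize_fringes,
)

errors = {n: [] for n in (3, 4, 5, 6, 12)}
for seed in range(6):
    ph = make_phantom(128, seed=seed, preset="flat")
    fr = synthesize_fringes(ph, AcquisitionConfig(n_spectral_pixels=512, noise_seed=seed))
    ref = process(fr)
    truth = BoundaryTrace(depth_um=ph.csi_truth_um, source="truth",
                          axial_pitch_um=ref.axial_pitch_um)
    for n in errors:
        b = ref if n == 12 else process(
            quantize_fringe(fr, n), reference_window=ref.display_window_db
        )
        errors[n].append(boundary_error(segment_csi(b), truth).mean_abs_error_um)

print("bits   mean CSI error (um)")
for n, e in errors.items():
    print(f"{n:4d}   {np.mean(e):6.1f}")
# 12-bit errors of a pixel or two reflect the speckle-limited fuzziness of
# the boundary itself; low-bit errors an order of magnitude larger show the
# boundary drowning in quantization noise.
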