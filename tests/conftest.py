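"""Shared fixtures: simulated scene banks and trained smoke models.

Everything is generated at test time from fixed seeds; the heavier banks are
session-scoped so the physics, metric and segmentation tests share one set
of simulated acquisitions.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from octbit.harness import _sub
from octbit.octproc import process
from octbit.phantom import AcquisitionConfig, make_phantom, synthesize_fringes
from octbit.quantize import quantize_fringe

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

SUITE_SEED = 20260927


def simulate_scene(seed: int, preset: str, width: int = 128, bits=(3, 4, 5, 6, 7, 8)):
    """One scene: phantom, 12-bit B-scan and every requested low-bit variant
    rendered through the shared 12-bit display window."""
    ph = make_phantom(width, seed=_sub(seed, 2), preset=preset)
    acq = AcquisitionConfig(n_spectral_pixels=512, noise_seed=_sub(seed, 3))
    fr12 = synthesize_fringes(ph, acq)
    b12 = process(fr12)
    variants = {
        n: process(quantize_fringe(fr12, n), reference_window=b12.display_window_db)
        for n in bits
    }
    return {"phantom": ph, "fringe12": fr12, "b12": b12, "variants": variants}


@pytest.fixture(scope="session")
def curved_bank():
    """20 curved-preset scenes with variants at 3..8 bits — the bank for the
    bit-depth degradation statistics."""
    return [simulate_scene(SUITE_SEED + i, "curved") for i in range(20)]


# the segmentation bank keeps native axial pitch but crops to the 128-row
# band that holds the retina, choroid and upper sclera, so the translation
# models spend their capacity on the anatomy rather than empty vitreous
SEG_CROP_TOP = 56


def crop_to_anatomy(b, top: int = SEG_CROP_TOP, rows: int = 128):
    from octbit.octproc import BScan

    return BScan(
        image=b.image[top : top + rows],
        axial_pitch_um=b.axial_pitch_um,
        bit_depth_tag=b.bit_depth_tag,
        display_window_db=b.display_window_db,
        meta=dict(b.meta, crop_top=top),
    )


@pytest.fixture(scope="session")
def flat_bank():
    """40 flat-preset scenes (CSI truth constant per scene), cropped to the
    anatomy band at native pitch — the segmentation study bank."""
    scenes = []
    for i in range(40):
        s = simulate_scene(SUITE_SEED + 1000 + i, "flat", bits=(3, 4, 5, 6))
        pitch = s["b12"].axial_pitch_um
        scenes.append(
            {
                "truth_um": s["phantom"].csi_truth_um - SEG_CROP_TOP * pitch,
                "pitch": pitch,
                "b12": crop_to_anatomy(s["b12"]),
                "variants": {n: crop_to_anatomy(b) for n, b in s["variants"].items()},
            }
        )
    return scenes


@pytest.fixture(scope="session")
def seg_models(flat_bank):
    """Small per-bit-depth generators trained on the flat bank's first 28
    scenes (the remaining 12 are the held-out test scenes)."""
    from octbit.gan import GanConfig, PairedSample, train

    models = {}
    for n in (3, 4, 5, 6):
        pairs = [
            PairedSample(
                x=s["variants"][n].image, y=s["b12"].image, scene_id=str(i), bit_depth=n
            )
            for i, s in enumerate(flat_bank[:28])
        ]
        cfg = GanConfig(
            image_size=128, base_channels=16, n_down_levels=4, d_base_channels=16,
            d_n_layers=2, batch_size=4, epochs=12, seed=_sub(SUITE_SEED, 40, n),
        )
        models[n], _ = train(pairs, cfg)
    return models


@pytest.fixture(scope="session")
def smoke_gan():
    """The 4-bit smoke study: 200 training pairs + 24 held-out test pairs at
    64x64, model trained 25 epochs.  Returns (generator, test_pairs)."""
    from octbit.gan import GanConfig, PairedSample, train
    from octbit.octproc import resize_image

    def pairs_for(indices):
        out = []
        for i in indices:
            s = simulate_scene(SUITE_SEED + 2000 + i, "curved", width=64, bits=(4,))
            out.append(
                PairedSample(
                    x=resize_image(s["variants"][4].image, 64),
                    y=resize_image(s["b12"].image, 64),
                    scene_id=str(i),
                    bit_depth=4,
                )
            )
        return out

    train_pairs = pairs_for(range(200))
    test_pairs = pairs_for(range(200, 224))
    cfg = GanConfig(
        image_size=64, base_channels=16, n_down_levels=4, d_base_channels=16,
        d_n_layers=2, batch_size=16, epochs=25, seed=_sub(SUITE_SEED, 70),
    )
    G, _ = train(train_pairs, cfg)
    return G, test_pairs
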