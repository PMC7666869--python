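"""Run a miniature end-to-end experiment and print its reports.

Builds a 10-scene dataset (3- and 4-bit variants plus 12-bit references),
trains one small model per bit depth, and emits the quality table
(bit depth x original/reconstructed, mean +/- std of each metric) and the
CSI segmentation summary — the same report structure a full study produces.
"""

import tempfile

from octbit import ExperimentConfig, GanConfig, run_experiment

with tempfile.TemporaryDirectory() as out:
    cfg = ExperimentConfig(
        preset="curved", n_scenes=10, seed=3, bit_depths=(3, 4),
        segment_bit_depths=(4,), width=64, n_spectral_pixels=512,
        out_dir=out, make_plots=False,
        gan=GanConfig(image_size=32, base_channels=8, n_down_levels=3,
                      d_base_channels=8, d_n_layers=2, batch_size=4, epochs=4),
    )
    bundle = run_experiment(cfg)
    print(bundle["quality"].to_string(index=False))
    print()
    print(bundle["segmentation"].to_string(index=False))
# At this illustrative scale (a handful of scenes, 4 epochs) the models are
# deliberately undertrained and reconstruction does not yet win; see
# examples/03_train_and_reconstruct.py or scripts/acceptance.py for budgets
# at which the reconstructed rows overtake the originals.
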