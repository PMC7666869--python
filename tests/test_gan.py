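"""Conditional GAN: architecture contracts, loss closed forms, training
behavior, checkpoints."""

import numpy as np
import pytest

from octbit.gan import (
    GanConfig,
    PairedSample,
    build_discriminator,
    build_generator,
    discriminator_loss,
    generator_loss,
    load_checkpoint,
    reconstruct,
    save_checkpoint,
    train,
)

TINY = dict(
    image_size=32, base_channels=8, n_down_levels=3, d_base_channels=8,
    d_n_layers=2, batch_size=4, epochs=3,
)


def toy_pairs(n=12, size=32, bits=4, seed=0):
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        y = np.clip(
            0.15
            + 0.7 * np.exp(-0.5 * ((np.arange(size)[:, None] - rng.uniform(8, 24)) / 4) ** 2)
            * np.ones((1, size))
            + 0.05 * rng.standard_normal((size, size)),
            0, 1,
        )
        x = np.floor(y * 2**bits) / 2**bits
        pairs.append(PairedSample(x=x, y=y, scene_id=f"s{i}", bit_depth=bits))
    return pairs


class TestArchitecture:
    def test_generator_preserves_shape(self):
        cfg = GanConfig(image_size=64, base_channels=8, n_down_levels=4)
        G = build_generator(cfg)
        out = G.forward(np.zeros((2, 1, 64, 64)))
        assert out.shape == (2, 1, 64, 64)

    def test_skip_ablation_changes_parameter_count(self):
        cfg = GanConfig(**TINY)
        n_with = sum(p.v.size for p in build_generator(cfg).params())
        cfg_no = GanConfig(**{**TINY, "use_skips": False})
        n_without = sum(p.v.size for p in build_generator(cfg_no).params())
        assert n_with > n_without

    def test_same_seed_gives_identical_weights(self):
        cfg = GanConfig(**TINY, seed=7)
        a, b = build_generator(cfg), build_generator(cfg)
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.v, pb.v)
        da, db = build_discriminator(cfg), build_discriminator(cfg)
        for pa, pb in zip(da.params(), db.params()):
            assert np.array_equal(pa.v, pb.v)

    def test_discriminator_outputs_patch_grid(self):
        cfg = GanConfig(image_size=256)
        D = build_discriminator(cfg)
        out = D.forward(np.zeros((1, 2, 256, 256)))
        assert out.ndim == 4 and out.shape[1] == 1
        side = out.shape[2]
        assert 1 < side < 256  # a patch map, not a scalar and not per-pixel

    def test_patch_grid_side_follows_stride_arithmetic(self):
        """Three stride-2 stages then two stride-1 (k=4, pad=1) convs give
        side = n/8 - 2; the grid side roughly doubles with the input side."""
        cfg = GanConfig(image_size=256)
        D = build_discriminator(cfg)
        for n in (128, 256):
            side = D.forward(np.zeros((1, 2, n, n))).shape[2]
            assert side == n // 8 - 2

    def test_default_receptive_field_is_70(self):
        assert build_discriminator(GanConfig()).receptive_field == 70

    def test_incompatible_size_rejected(self):
        with pytest.raises(ValueError):
            GanConfig(image_size=16, n_down_levels=5)
        with pytest.raises(ValueError):
            GanConfig(image_size=48)


class TestLosses:
    def test_discriminator_loss_at_half_scores(self):
        s = np.full((4, 1, 3, 3), 0.5)
        assert discriminator_loss(s, s) == pytest.approx(2 * np.log(2), abs=1e-6)

    def test_perfect_discriminator_loss_vanishes(self):
        eps = 1e-9
        real = np.full((2, 2), 1 - eps)
        fake = np.full((2, 2), eps)
        assert discriminator_loss(real, fake) == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_fixed_point(self):
        s = np.full((3, 3), 0.5)
        assert discriminator_loss(s, s) == discriminator_loss(s.copy(), s.copy())

    def test_generator_loss_perfect_reconstruction(self):
        y = np.random.default_rng(0).random((8, 8))
        s = np.full((2, 2), 0.5)
        assert generator_loss(s, y, y, 10.0) == pytest.approx(np.log(2), abs=1e-6)

    def test_lambda_zero_ignores_reference(self):
        rng = np.random.default_rng(1)
        s = np.full((2, 2), 0.3)
        g = rng.random((8, 8))
        assert generator_loss(s, g, rng.random((8, 8)), 0.0) == generator_loss(
            s, g, rng.random((8, 8)), 0.0
        )

    def test_constant_offset_gives_lambda_times_offset(self):
        y = np.random.default_rng(2).random((8, 8)) * 0.5
        c = 0.125
        s = np.full((2, 2), 0.5)
        expected = np.log(2) + 10.0 * c
        assert generator_loss(s, y + c, y, 10.0) == pytest.approx(expected, abs=1e-6)

    def test_logit_and_probability_forms_agree(self):
        logits = np.array([[0.3, -1.2], [2.0, 0.0]])
        probs = 1 / (1 + np.exp(-logits))
        a = discriminator_loss(logits, -logits, from_logits=True)
        b = discriminator_loss(probs, 1 - probs)
        assert a == pytest.approx(b, rel=1e-9)

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            discriminator_loss(np.array([0.0]), np.array([0.5]))
        with pytest.raises(FloatingPointError):
            discriminator_loss(np.array([np.nan]), np.array([0.5]), from_logits=True)
        with pytest.raises(ValueError):
            generator_loss(np.array([0.5]), np.zeros((2, 2)), np.zeros((3, 3)), 1.0)


class TestTraining:
    def test_l1_decreases_on_toy_task(self):
        pairs = toy_pairs(12)
        cfg = GanConfig(**TINY, seed=3)
        _, hist = train(pairs, cfg)
        assert hist.l1[-1] < hist.l1[0]
        assert all(np.isfinite(hist.g_loss)) and all(np.isfinite(hist.d_loss))

    def test_identical_seeds_reproduce_losses(self):
        pairs = toy_pairs(8)
        cfg = GanConfig(**{**TINY, "epochs": 2}, seed=5)
        _, h1 = train(pairs, cfg)
        _, h2 = train(pairs, cfg)
        assert h1.g_loss == h2.g_loss and h1.d_loss == h2.d_loss

    def test_generator_only_baseline_minimizes_l1_at_least_as_well(self):
        """With the discriminator disabled the objective is pure L1, so under
        an equal budget the baseline's final training L1 cannot exceed the
        adversarial model's."""
        pairs = toy_pairs(12, seed=4)
        # a modest L1 weight keeps the adversarial term non-negligible, so
        # the two objectives genuinely diverge within the toy budget
        cfg_adv = GanConfig(**{**TINY, "epochs": 25, "lambda_l1": 2.0}, seed=6)
        cfg_l1 = GanConfig(
            **{**TINY, "epochs": 25, "lambda_l1": 2.0}, seed=6, adversarial=False
        )
        _, h_adv = train(pairs, cfg_adv)
        _, h_l1 = train(pairs, cfg_l1)
        assert h_l1.l1[-1] <= h_adv.l1[-1] + 1e-6
        assert all(d == 0.0 for d in h_l1.d_loss)

    def test_empty_or_inconsistent_datasets_rejected(self):
        cfg = GanConfig(**TINY)
        with pytest.raises(ValueError):
            train([], cfg)
        bad = toy_pairs(2) + [
            PairedSample(x=np.zeros((16, 16)), y=np.zeros((16, 16)), bit_depth=4)
        ]
        with pytest.raises(ValueError):
            train(bad, cfg)


@pytest.fixture(scope="module")
def trained():
    pairs = toy_pairs(8, seed=7)
    cfg = GanConfig(**{**TINY, "epochs": 2}, seed=8)
    G, _ = train(pairs, cfg)
    return G


class TestReconstruct:

    def test_output_range_and_shape(self, trained):
        x = np.random.default_rng(9).random((32, 32))
        out = reconstruct(trained, x)
        assert out.shape == x.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_untrained_generator_output_still_bounded(self):
        G = build_generator(GanConfig(**TINY, seed=10))
        out = reconstruct(G, np.random.default_rng(10).random((32, 32)))
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_inference_is_deterministic(self, trained):
        x = np.random.default_rng(11).random((32, 32))
        assert np.array_equal(reconstruct(trained, x), reconstruct(trained, x))

    def test_batch_matches_one_by_one(self, trained):
        xs = np.random.default_rng(12).random((4, 32, 32))
        batch = reconstruct(trained, xs)
        singles = np.stack([reconstruct(trained, x) for x in xs])
        assert np.allclose(batch, singles, atol=1e-12)

    def test_resizes_foreign_shapes_in_and_out(self, trained):
        x = np.random.default_rng(13).random((80, 40))
        out = reconstruct(trained, x)
        assert out.shape == (80, 40)

    def test_checkpoint_round_trip(self, trained, tmp_path):
        cfg = GanConfig(**{**TINY, "epochs": 2}, seed=8)
        p = tmp_path / "g.npz"
        save_checkpoint(trained, cfg, p)
        G2, cfg2 = load_checkpoint(p)
        assert cfg2 == cfg
        x = np.random.default_rng(14).random((32, 32))
        assert np.allclose(reconstruct(trained, x), reconstruct(G2, x), atol=1e-12)


def test_validation_metrics_recorded_per_epoch():
    pairs = toy_pairs(8, seed=20)
    val = toy_pairs(2, seed=21)
    cfg = GanConfig(**{**TINY, "epochs": 2}, seed=22)
    from octbit.gan import train as _train

    _, hist = _train(pairs, cfg, val_set=val)
    assert len(hist.val_psnr) == 2 and len(hist.val_msssim) == 2
    assert all(np.isfinite(hist.val_psnr)) and all(np.isfinite(hist.val_msssim))


def test_resize_decoder_variant_trains_and_reconstructs():
    """The upsample-then-convolve decoder is a drop-in alternative to the
    fractionally strided one: same shapes, deterministic, finite losses."""
    pairs = toy_pairs(8, seed=30)
    cfg = GanConfig(**{**TINY, "epochs": 2}, seed=31, up_mode="resize")
    G, hist = train(pairs, cfg)
    assert all(np.isfinite(hist.g_loss))
    out = reconstruct(G, pairs[0].x)
    assert out.shape == pairs[0].x.shape and 0.0 <= out.min() <= out.max() <= 1.0
    with pytest.raises(ValueError):
        GanConfig(**TINY, up_mode="bilinear")
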