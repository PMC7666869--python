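"""Paired low-to-high bit-depth B-scan translation with a conditional GAN.

A U-shape encoder–decoder generator G (skip connections between mirror
levels) maps an N-bit B-scan x toward its 12-bit reference y; a patch
discriminator D scores (x, candidate) pairs on a grid of overlapping
patches, penalizing high-frequency structure locally.  The objective is

    L_GAN(G, D) = E[log D(x, y)] + E[log(1 - D(x, G(x)))]
    G* = arg min_G max_D  L_GAN(G, D) + lambda * E[ |y - G(x)|_1 ]

trained by alternating Adam updates.  The generator's adversarial term is
realized in the standard non-saturating form (-log D(x, G(x))) computed on
logits for stability.  Disabling the discriminator leaves a pure-L1 U-shape
baseline — the "U-Net" comparator.

Networks run on the CPU via the layer library in :mod:`octbit._nn`; image
values are mapped [0,1] -> [-1,1] at the input and back at the output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Adam, BatchNorm2d, Conv2d, ConvTranspose2d, InstanceNorm2d, LeakyReLU, Module, ReLU, Sequential, Tanh, bce_logits
from .metrics import msssim, psnr
from .octproc import BScan, resize_image


@dataclass
class PairedSample:
    """Pixel-aligned (low-bit, 12-bit) B-scan pair from one scene."""

    x: np.ndarray
    y: np.ndarray
    scene_id: str = ""
    bit_depth: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("paired images must share a shape")


@dataclass
class GanConfig:
    """Hyperparameters; defaults follow the published training recipe
    (256x256 inputs, lambda=10, Adam 2e-4 with beta1=0.5, beta2=0.999,
    batch 16, 200 epochs)."""

    image_size: int = 256
    base_channels: int = 64
    n_down_levels: int = 8
    d_base_channels: int = 64
    d_n_layers: int = 3
    lambda_l1: float = 10.0
    lr_g: float = 2e-4
    lr_d: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    batch_size: int = 16
    epochs: int = 200
    seed: int = 0
    norm_kind: str = "batch"  # or "instance"
    up_mode: str = "deconv"  # "deconv" (fractionally strided) or "resize"
    use_skips: bool = True
    adversarial: bool = True
    lr_decay: bool = False

    def __post_init__(self) -> None:
        s = self.image_size
        if s < 1 or (s & (s - 1)) != 0:
            raise ValueError("image_size must be a power of two")
        if s < 2**self.n_down_levels:
            raise ValueError(
                f"image_size {s} incompatible with {self.n_down_levels} "
                "halving levels"
            )
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")
        if self.norm_kind not in ("batch", "instance"):
            raise ValueError(f"unknown norm_kind {self.norm_kind!r}")
        if self.up_mode not in ("resize", "deconv"):
            raise ValueError(f"unknown up_mode {self.up_mode!r}")


@dataclass
class TrainHistory:
    g_loss: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    l1: list[float] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)
    val_msssim: list[float] = field(default_factory=list)


def _norm(kind: str, ch: int, rng) -> Module:
    return BatchNorm2d(ch, rng=rng) if kind == "batch" else InstanceNorm2d(ch, rng=rng)


class UnetGenerator(Module):
    """Encoder–decoder with skip connections between mirror-symmetric levels.

    Channel widths double per level and are capped at 8x the base; the
    innermost level has no normalization, the output layer ends in tanh.
    """

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        n = cfg.n_down_levels
        self.cfg = cfg
        self.image_size = cfg.image_size
        ch = [1] + [cfg.base_channels * min(2 ** i, 8) for i in range(n)]
        self.down: list[Sequential] = []
        for i in range(1, n + 1):
            layers = []
            if i > 1:
                layers.append(LeakyReLU(0.2))
            layers.append(Conv2d(ch[i - 1], ch[i], 4, 2, 1, rng=rng))
            if 1 < i < n:
                layers.append(_norm(cfg.norm_kind, ch[i], rng))
            self.down.append(Sequential(*layers))
        self.up: list[Sequential] = []
        for i in range(n, 0, -1):
            in_ch = ch[i] if (i == n or not cfg.use_skips) else 2 * ch[i]
            out_ch = ch[i - 1]
            if cfg.up_mode == "resize":
                # upsample-then-convolve: avoids the uneven kernel overlap of
                # strided transposed convolutions, whose periodic intensity
                # stripes segmenters mistake for laterally consistent edges
                up: list[Module] = [
                    ReLU(), _nn.Upsample2x(), Conv2d(in_ch, out_ch, 3, 1, 1, rng=rng)
                ]
            else:
                up = [ReLU(), ConvTranspose2d(in_ch, out_ch, 4, 2, 1, rng=rng)]
            layers = up
            if i > 1:
                layers.append(_norm(cfg.norm_kind, out_ch, rng))
            else:
                layers.append(Tanh())
            self.up.append(Sequential(*layers))
        self.children = self.down + self.up

    def params(self):
        return [p for m in self.children for p in m.params()]

    def forward(self, x):
        n = self.cfg.n_down_levels
        skips = []
        h = x
        for blk in self.down:
            h = blk.forward(h)
            skips.append(h)
        u = None
        self._used_skip = []
        for j, blk in enumerate(self.up):
            i = n - j  # level index n..1
            if i == n:
                inp = skips[-1]
            elif self.cfg.use_skips:
                inp = np.concatenate([u, skips[i - 1]], axis=1)
            else:
                inp = u
            u = blk.forward(inp)
        return u

    def backward(self, gout):
        n = self.cfg.n_down_levels
        skip_grads = [None] * n
        g = gout
        for j in reversed(range(len(self.up))):
            i = n - j
            gi = self.up[j].backward(g)
            if i == n:
                skip_grads[n - 1] = _acc(skip_grads[n - 1], gi)
                g = None
            elif self.cfg.use_skips:
                cu = gi.shape[1] // 2
                g_up, g_skip = gi[:, :cu], gi[:, cu:]
                skip_grads[i - 1] = _acc(skip_grads[i - 1], g_skip)
                g = g_up
            else:
                g = gi
            if i < n:
                # gradient flowing back into the encoder chain at level i+1..
                pass
        # now walk the encoder backwards, merging skip gradients
        g = None
        for i in reversed(range(n)):
            g = _acc(g, skip_grads[i])
            g = self.down[i].backward(g)
        return g


def _acc(a, b):
    if a is None:
        return b
    if b is None:
        return a
    return a + b


class PatchDiscriminator(Module):
    """PatchGAN: maps the channel-concatenated (x, candidate) pair to a 2-D
    grid of patch logits.  With the default three stride-2 stages each logit
    sees a ~70x70 px receptive field."""

    def __init__(self, cfg: GanConfig, rng: np.random.Generator):
        b = cfg.d_base_channels
        nl = cfg.d_n_layers
        layers = [Conv2d(2, b, 4, 2, 1, rng=rng), LeakyReLU(0.2)]
        ch = b
        for i in range(1, nl):
            nxt = min(ch * 2, 8 * b)
            layers += [Conv2d(ch, nxt, 4, 2, 1, rng=rng), _norm(cfg.norm_kind, nxt, rng), LeakyReLU(0.2)]
            ch = nxt
        nxt = min(ch * 2, 8 * b)
        layers += [Conv2d(ch, nxt, 4, 1, 1, rng=rng), _norm(cfg.norm_kind, nxt, rng), LeakyReLU(0.2)]
        layers += [Conv2d(nxt, 1, 4, 1, 1, rng=rng)]
        self.net = Sequential(*layers)
        self.children = [self.net]

    def params(self):
        return self.net.params()

    def forward(self, x):
        return self.net.forward(x)

    def backward(self, g):
        return self.net.backward(g)

    @property
    def receptive_field(self) -> int:
        """Receptive field of one output logit, from the stride/kernel chain."""
        rf = 1
        convs = [m for m in self.net.children if isinstance(m, Conv2d)]
        for c in reversed(convs):
            rf = rf * c.stride + (c.k - c.stride)
        return rf


def build_generator(cfg: GanConfig, seed: int | None = None) -> UnetGenerator:
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 101])
    return UnetGenerator(cfg, rng)


def build_discriminator(cfg: GanConfig, seed: int | None = None) -> PatchDiscriminator:
    rng = np.random.default_rng([cfg.seed if seed is None else seed, 202])
    return PatchDiscriminator(cfg, rng)


# ---------------------------------------------------------------------------
# losses


def _as_prob(scores, from_logits):
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise FloatingPointError("non-finite discriminator scores")
    if from_logits:
        s = 1.0 / (1.0 + np.exp(-s))
    elif np.any(s <= 0) or np.any(s >= 1):
        raise ValueError("probability scores must lie in (0, 1)")
    return s


def discriminator_loss(d_real_scores, d_fake_scores, from_logits: bool = False) -> float:
    """Loss the discriminator descends: ``-[mean log D(x,y) +
    mean log(1 - D(x,G(x)))]`` over patch scores."""
    pr = _as_prob(d_real_scores, from_logits)
    pf = _as_prob(d_fake_scores, from_logits)
    return float(-(np.mean(np.log(pr)) + np.mean(np.log1p(-pf))))


def generator_loss(d_fake_scores, g_out, y, lambda_l1: float, from_logits: bool = False) -> float:
    """Non-saturating adversarial term plus the weighted L1 fidelity term:
    ``-mean log D(x, G(x)) + lambda * mean |y - G(x)|``."""
    g_out = np.asarray(g_out, dtype=float)
    y = np.asarray(y, dtype=float)
    if g_out.shape != y.shape:
        raise ValueError("generator output and reference shapes differ")
    pf = _as_prob(d_fake_scores, from_logits)
    adv = float(-np.mean(np.log(pf)))
    return adv + float(lambda_l1) * float(np.mean(np.abs(y - g_out)))


# ---------------------------------------------------------------------------
# training


def _stack(images) -> np.ndarray:
    arr = np.stack([np.asarray(im, dtype=float) for im in images])
    return arr[:, None] * 2.0 - 1.0  # [0,1] -> [-1,1], NCHW


def train(
    dataset: list[PairedSample],
    cfg: GanConfig,
    val_set: list[PairedSample] | None = None,
    checkpoint_path=None,
    progress: bool = False,
) -> tuple[UnetGenerator, TrainHistory]:
    """Alternating D/G Adam updates over shuffled mini-batches.

    All randomness (weights, shuffling) derives from ``cfg.seed``; with a
    fixed seed the run is bit-reproducible.
    """
    if not dataset:
        raise ValueError("empty dataset")
    shapes = {p.x.shape for p in dataset}
    if len(shapes) != 1:
        raise ValueError(f"mixed image shapes in dataset: {shapes}")
    shape = next(iter(shapes))
    div = 2**cfg.n_down_levels
    if any(d % div != 0 or d < div for d in shape):
        raise ValueError(
            f"image shape {shape} not divisible by 2^{cfg.n_down_levels}"
        )
    bits = {p.bit_depth for p in dataset}
    if len(bits) > 1:
        raise ValueError(f"mixed bit depths in dataset: {bits}")

    G = build_generator(cfg)
    D = build_discriminator(cfg) if cfg.adversarial else None
    optG = Adam(G.params(), cfg.lr_g, cfg.beta1, cfg.beta2)
    optD = Adam(D.params(), cfg.lr_d, cfg.beta1, cfg.beta2) if D else None
    shuffle_rng = np.random.default_rng([cfg.seed, 303])

    X = _stack([p.x for p in dataset])
    Y = _stack([p.y for p in dataset])
    n = len(dataset)
    hist = TrainHistory()
    lam = cfg.lambda_l1

    for epoch in range(cfg.epochs):
        if cfg.lr_decay:
            scale = 1.0 - epoch / max(cfg.epochs, 1)
            optG.lr = cfg.lr_g * scale
            if optD:
                optD.lr = cfg.lr_d * scale
        order = shuffle_rng.permutation(n)
        ep_g, ep_d, ep_l1, nb = 0.0, 0.0, 0.0, 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            xb, yb = X[idx], Y[idx]
            G.train_mode(True)
            fake = G.forward(xb)

            d_adv_grad = None
            if D is not None:
                D.train_mode(True)
                # --- D step (fake detached: no grad into G here)
                D.zero_grad()
                lr_real, g_real = bce_logits(D.forward(np.concatenate([xb, yb], 1)), 1.0)
                D.backward(g_real)
                lr_fake, g_fake = bce_logits(D.forward(np.concatenate([xb, fake], 1)), 0.0)
                D.backward(g_fake)
                optD.step()
                ep_d += lr_real + lr_fake
                # --- adversarial gradient for G (non-saturating)
                D.zero_grad()
                ladv, g_adv = bce_logits(D.forward(np.concatenate([xb, fake], 1)), 1.0)
                gin = D.backward(g_adv)
                d_adv_grad = gin[:, 1:2]
                D.zero_grad()
            else:
                ladv = 0.0

            l1 = float(np.mean(np.abs(yb - fake)))
            g_l1 = lam * np.sign(fake - yb) / fake.size
            gG = g_l1 if d_adv_grad is None else g_l1 + d_adv_grad
            G.zero_grad()
            G.backward(gG)
            optG.step()
            ep_g += ladv + lam * l1
            ep_l1 += l1
            nb += 1

        hist.g_loss.append(ep_g / nb)
        hist.d_loss.append(ep_d / nb)
        hist.l1.append(ep_l1 / nb)
        if val_set:
            ps, ms = [], []
            for p in val_set:
                r = reconstruct(G, p.x)
                ps.append(psnr(r, p.y))
                ms.append(msssim(r, p.y))
            hist.val_psnr.append(float(np.mean([v for v in ps if math.isfinite(v)])))
            hist.val_msssim.append(float(np.mean(ms)))
        if progress:
            print(
                f"epoch {epoch + 1}/{cfg.epochs}  g={hist.g_loss[-1]:.4f} "
                f"d={hist.d_loss[-1]:.4f} l1={hist.l1[-1]:.4f}"
            )

    if checkpoint_path is not None:
        save_checkpoint(G, cfg, checkpoint_path)
    return G, hist


def reconstruct(generator: UnetGenerator, x):
    """Translate a low-bit image (or BScan, or stack) through the generator.

    Inputs are resized to the model's training size if needed and the output
    resized back; results are deterministic in inference mode and clipped
    to [0, 1].
    """
    if isinstance(x, BScan):
        out = reconstruct(generator, x.image)
        return BScan(
            image=out,
            axial_pitch_um=x.axial_pitch_um,
            bit_depth_tag=x.bit_depth_tag,
            display_window_db=x.display_window_db,
            meta={**x.meta, "reconstructed": True},
        )
    x = np.asarray(x, dtype=float)
    if x.ndim == 3:
        return np.stack([reconstruct(generator, im) for im in x])
    s = generator.image_size
    orig_shape = x.shape
    # the fully convolutional net accepts any shape divisible by the level
    # count; only incompatible shapes are resized through the model size
    div = 2 ** generator.cfg.n_down_levels
    native = all(d % div == 0 and d >= div for d in x.shape)
    img = x if native else resize_image(x, (s, s))
    generator.train_mode(False)
    out = generator.forward(img[None, None] * 2.0 - 1.0)[0, 0]
    out = np.clip((out + 1.0) / 2.0, 0.0, 1.0)
    if out.shape != orig_shape:
        out = resize_image(out, orig_shape)
    return out


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(generator: UnetGenerator, cfg: GanConfig, path) -> None:
    """Serialized generator weights plus a JSON sidecar of the config."""
    path = Path(path)
    arrays = {f"p{i}": p.v for i, p in enumerate(generator.params())}
    # batch-norm running statistics travel with the weights
    stats = {}
    for i, m in enumerate(_iter_modules(generator)):
        if isinstance(m, BatchNorm2d):
            stats[f"rm{i}"] = m.run_mean
            stats[f"rv{i}"] = m.run_var
    np.savez(path, **arrays, **stats)
    side = Path(str(path) + ".json")
    side.write_text(json.dumps(asdict(cfg)))


def load_checkpoint(path) -> tuple[UnetGenerator, GanConfig]:
    path = Path(path)
    side = Path(str(path) + ".json")
    if not side.exists():
        raise FileNotFoundError(f"missing checkpoint sidecar {side}")
    cfg = GanConfig(**json.loads(side.read_text()))
    G = build_generator(cfg)
    data = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
    for i, p in enumerate(G.params()):
        p.v[...] = data[f"p{i}"]
    for i, m in enumerate(_iter_modules(G)):
        if isinstance(m, BatchNorm2d) and f"rm{i}" in data:
            m.run_mean[...] = data[f"rm{i}"]
            m.run_var[...] = data[f"rv{i}"]
    return G, cfg


def _iter_modules(root: Module):
    out = []

    def walk(m):
        out.append(m)
        for c in getattr(m, "children", []):
            walk(c)

    walk(root)
    return out
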