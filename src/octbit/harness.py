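"""Experiment orchestration: dataset builder, per-bit-depth train/evaluate
loops, quality and segmentation reports, hyperparameter sweeps.

A dataset is a set of simulated scenes; every scene yields one 12-bit
reference B-scan and one B-scan per reduced bit depth, all rendered through
the scene's shared 12-bit display window so the variants live on one
intensity scale.  Scenes play the role of subjects for the disjoint
train/val/test split.  All randomness flows from one root seed through named
substreams (phantom geometry, detection noise, network weights, shuffling),
so any component can be reproduced in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .gan import GanConfig, PairedSample, TrainHistory, UnetGenerator, reconstruct, train
from .metrics import evaluate_set, msssim
from .octproc import ProcConfig, process, read_bscan, resize_image, write_bscan
from .phantom import AcquisitionConfig, make_phantom, synthesize_fringes, write_phantom_truth
from .quantize import quantize_fringe
from .segment import BoundaryTrace, boundary_error, segment_csi

SWEEP_AXES = ("batch_size", "lambda_l1", "epochs", "learning_rate", "image_size")


def _sub(root: int, *tags: int) -> int:
    """Named deterministic substream seed below 2**31."""
    h = np.random.SeedSequence([int(root)] + [int(t) for t in tags])
    return int(h.generate_state(1, np.uint32)[0] % (2**31 - 1))


@dataclass
class ExperimentConfig:
    preset: str = "curved"
    n_scenes: int = 40
    seed: int = 0
    bit_depths: tuple[int, ...] = (3, 4, 5, 6, 7, 8)
    segment_bit_depths: tuple[int, ...] = (3, 4, 5, 6)
    width: int = 128
    n_spectral_pixels: int = 512
    split: tuple[float, float, float] = (0.7, 0.1, 0.2)
    proc: ProcConfig = field(default_factory=ProcConfig)
    acq: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    gan: GanConfig = field(default_factory=lambda: GanConfig(
        image_size=64, base_channels=16, n_down_levels=4,
        d_base_channels=16, d_n_layers=2, batch_size=8, epochs=15,
    ))
    out_dir: str = "octbit_out"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if self.n_scenes < 1:
            raise ValueError("n_scenes must be >= 1")
        bad = [b for b in self.bit_depths if not 1 <= b <= 12]
        if bad:
            raise ValueError(f"bit depths outside [1, 12]: {bad}")


@dataclass
class DatasetManifest:
    root: str
    seed: int
    scenes: list[dict]

    def scene_ids(self, split: str | None = None) -> list[str]:
        return [s["id"] for s in self.scenes if split is None or s["split"] == split]

    def path(self, scene_id: str, bits: int) -> Path:
        s = next(s for s in self.scenes if s["id"] == scene_id)
        return Path(self.root) / s["bscans"][str(bits)]

    def truth_path(self, scene_id: str) -> Path:
        s = next(s for s in self.scenes if s["id"] == scene_id)
        return Path(self.root) / s["truth"]

    def validate(self) -> None:
        tags = {}
        for s in self.scenes:
            tags.setdefault(s["split"], set()).add(s["id"])
            for rel in list(s["bscans"].values()) + [s["truth"]]:
                if not (Path(self.root) / rel).exists():
                    raise FileNotFoundError(rel)
        ids = [s["id"] for s in self.scenes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate scene ids")
        splits = list(tags.values())
        for i in range(len(splits)):
            for j in range(i + 1, len(splits)):
                if splits[i] & splits[j]:
                    raise ValueError("scene appears in two splits")

    def save(self, path=None) -> Path:
        p = Path(path) if path else Path(self.root) / "manifest.json"
        p.write_text(json.dumps({"seed": self.seed, "scenes": self.scenes}, indent=1))
        return p

    @classmethod
    def load(cls, path) -> "DatasetManifest":
        path = Path(path)
        d = json.loads(path.read_text())
        return cls(root=str(path.parent), seed=d["seed"], scenes=d["scenes"])


def _split_tags(n: int, fractions, rng) -> list[str]:
    n_train = int(n * fractions[0])
    n_val = int(n * fractions[1])
    tags = ["train"] * n_train + ["val"] * n_val + ["test"] * (n - n_train - n_val)
    perm = rng.permutation(n)
    out = [""] * n
    for pos, t in zip(perm, tags):
        out[pos] = t
    return out


def build_dataset(cfg: ExperimentConfig) -> DatasetManifest:
    """Simulate scenes, process all bit-depth variants, write files + manifest.

    Per scene: 12-bit fringe -> quantize to each requested depth -> process
    with the scene's 12-bit display window -> B-scan TIFFs on disk.
    Deterministic for a fixed root seed.
    """
    out = Path(cfg.out_dir)
    (out / "scenes").mkdir(parents=True, exist_ok=True)
    split_rng = np.random.default_rng(_sub(cfg.seed, 1))
    tags = _split_tags(cfg.n_scenes, cfg.split, split_rng)
    bits_all = sorted(set(cfg.bit_depths) | {12})
    scenes = []
    for i in range(cfg.n_scenes):
        sid = f"scene_{i:04d}"
        sdir = out / "scenes" / sid
        sdir.mkdir(exist_ok=True)
        ph = make_phantom(cfg.width, seed=_sub(cfg.seed, 2, i), preset=cfg.preset)
        acq = replace(
            cfg.acq,
            n_spectral_pixels=cfg.n_spectral_pixels,
            noise_seed=_sub(cfg.seed, 3, i),
        )
        fr12 = synthesize_fringes(ph, acq)
        b12 = process(fr12, cfg.proc)
        write_phantom_truth(ph, sdir / "truth.json")
        paths = {}
        for n_bits in bits_all:
            if n_bits == 12:
                b = b12
            else:
                b = process(
                    quantize_fringe(fr12, n_bits), cfg.proc,
                    reference_window=b12.display_window_db,
                )
            rel = f"scenes/{sid}/bscan_{n_bits:02d}.tif"
            write_bscan(b, out / rel)
            paths[str(n_bits)] = rel
        scenes.append(
            {"id": sid, "split": tags[i], "truth": f"scenes/{sid}/truth.json",
             "bscans": paths}
        )
    manifest = DatasetManifest(root=str(out), seed=cfg.seed, scenes=scenes)
    manifest.validate()
    manifest.save()
    return manifest


def _load_pairs(
    manifest: DatasetManifest, scene_ids, bits: int, image_size: int
) -> list[PairedSample]:
    pairs = []
    for sid in scene_ids:
        x = read_bscan(manifest.path(sid, bits)).image
        y = read_bscan(manifest.path(sid, 12)).image
        pairs.append(
            PairedSample(
                x=resize_image(x, image_size),
                y=resize_image(y, image_size),
                scene_id=sid,
                bit_depth=bits,
            )
        )
    return pairs


def train_for_bits(
    manifest: DatasetManifest, bits: int, gan_cfg: GanConfig, seed: int
) -> tuple[UnetGenerator, TrainHistory]:
    """Train one model for one bit depth on the manifest's train split."""
    pairs = _load_pairs(manifest, manifest.scene_ids("train"), bits, gan_cfg.image_size)
    cfg = replace(gan_cfg, seed=_sub(seed, 4, bits))
    return train(pairs, cfg)


def run_experiment(cfg: ExperimentConfig, manifest: DatasetManifest | None = None) -> dict:
    """Full study: per bit depth, train a model on the train split and score
    originals and reconstructions on the test split; also run the CSI
    segmentation probe.  Returns a bundle of dataframes and paths."""
    out = Path(cfg.out_dir)
    if manifest is None:
        manifest = build_dataset(cfg)
    test_ids = manifest.scene_ids("test")
    if not test_ids:
        raise ValueError("test split is empty; increase n_scenes")

    eval_pairs, labels = [], []
    seg_rows = []
    generators = {}
    for bits in sorted(cfg.bit_depths):
        if bits == 12:
            continue
        G, _hist = train_for_bits(manifest, bits, cfg.gan, cfg.seed)
        generators[bits] = G
        for sid in test_ids:
            bx = read_bscan(manifest.path(sid, bits))
            by = read_bscan(manifest.path(sid, 12))
            x64 = resize_image(bx.image, cfg.gan.image_size)
            y64 = resize_image(by.image, cfg.gan.image_size)
            r64 = reconstruct(G, x64)
            eval_pairs += [(x64, y64), (r64, y64)]
            labels += [(bits, "original"), (bits, "reconstructed")]
            if bits in cfg.segment_bit_depths:
                truth_d = json.loads(manifest.truth_path(sid).read_text())
                truth = BoundaryTrace(
                    depth_um=np.asarray(truth_d["boundaries_um"]["CSI"]),
                    source="truth", axial_pitch_um=bx.axial_pitch_um,
                )
                rec_native = reconstruct(G, bx)  # resized in and back out
                for variant, b in (("original", bx), ("reconstructed", rec_native)):
                    rep = boundary_error(segment_csi(b), truth, bits, variant)
                    seg_rows.append(
                        dict(scene_id=sid, bit_depth=bits, variant=variant,
                             mean_abs_error_um=rep.mean_abs_error_um)
                    )

    report = evaluate_set(eval_pairs, labels)
    report_path = out / "quality_report.csv"
    report.to_csv(report_path)
    seg_df = pd.DataFrame(seg_rows)
    seg_path = out / "segmentation_report.csv"
    if not seg_df.empty:
        seg_summary = (
            seg_df.groupby(["bit_depth", "variant"], sort=True)["mean_abs_error_um"]
            .agg(["mean", "std", "count"]).reset_index()
        )
        seg_summary.to_csv(seg_path, index=False)
    else:
        seg_summary = pd.DataFrame()
    if cfg.make_plots:
        _plot_metrics(report.table, out / "metrics_vs_bit_depth.png")
    return {
        "manifest": manifest,
        "quality": report.table,
        "quality_csv": report_path,
        "segmentation": seg_summary,
        "segmentation_csv": seg_path,
        "generators": generators,
    }


def _plot_metrics(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    for ax, m in zip(axes, ("psnr", "msssim", "corr2")):
        for variant, color in (("original", "k"), ("reconstructed", "r")):
            sub = table[table["variant"] == variant]
            ax.errorbar(
                sub["bit_depth"], sub[f"{m}_mean"], yerr=sub[f"{m}_std"],
                fmt="s-" if variant == "original" else "o-", color=color,
                label=variant, capsize=3,
            )
        ax.set_xlabel("bit depth")
        ax.set_ylabel(m.upper())
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def run_sweep(
    cfg: ExperimentConfig, axis: str, values, bits: int = 4,
    manifest: DatasetManifest | None = None,
) -> pd.DataFrame:
    """MSSSIM-vs-value table for one hyperparameter axis at fixed others.

    The measure is the mean MSSSIM of test-split reconstructions against the
    12-bit references, one row per value of the swept axis.
    """
    if axis not in SWEEP_AXES:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {SWEEP_AXES}")
    if manifest is None:
        manifest = build_dataset(cfg)
    rows = []
    for v in values:
        g = cfg.gan
        if axis == "batch_size":
            g = replace(g, batch_size=int(v))
        elif axis == "lambda_l1":
            g = replace(g, lambda_l1=float(v))
        elif axis == "epochs":
            g = replace(g, epochs=int(v))
        elif axis == "learning_rate":
            g = replace(g, lr_g=float(v), lr_d=float(v))
        elif axis == "image_size":
            g = replace(g, image_size=int(v))
        G, _ = train_for_bits(manifest, bits, g, cfg.seed)
        ms = []
        for sid in manifest.scene_ids("test"):
            x = resize_image(read_bscan(manifest.path(sid, bits)).image, g.image_size)
            y = resize_image(read_bscan(manifest.path(sid, 12)).image, g.image_size)
            ms.append(msssim(reconstruct(G, x), y))
        rows.append({axis: v, "msssim_mean": float(np.mean(ms)),
                     "msssim_std": float(np.std(ms, ddof=1)) if len(ms) > 1 else 0.0})
    return pd.DataFrame(rows)
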