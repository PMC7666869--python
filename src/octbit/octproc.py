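"""SD-OCT post-processing: k-linearization, dispersion compensation, FFT,
logarithmic display mapping.

The chain turns a background-free spectral fringe into a B-scan:

1. resample the spectrum from its wavelength-uniform grid onto a uniform
   wavenumber grid (cubic interpolation) so the FFT yields sharp depth peaks;
2. form the analytic (complex) spectrum with a Hilbert transform along the
   spectral axis and multiply by ``exp(-i [a2 (k-k0)^2 + a3 (k-k0)^3])`` to
   cancel the dispersion imbalance;
3. FFT each A-scan, keep the positive-depth half, take the magnitude,
   ``20 log10(. + eps)``, and map a dB display window linearly to [0, 1].

The 12-bit image of a scene defines the display window applied to all of
its lower-bit variants, so images at different bit depths live on one common
intensity scale and PSNR/MSSSIM comparisons across bit depths are coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline, interp1d
from scipy.signal import hilbert
from skimage.transform import resize as _sk_resize

from .quantize import BackgroundFreeFringe, SpectralFringe, subtract_background


@dataclass
class BScan:
    """Processed log-magnitude OCT image, display-normalized to [0, 1]."""

    image: np.ndarray
    axial_pitch_um: float
    bit_depth_tag: int
    display_window_db: tuple[float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim != 2:
            raise ValueError("BScan image must be 2-D")
        if self.image.min() < -1e-12 or self.image.max() > 1 + 1e-12:
            raise ValueError("BScan image values must lie in [0, 1]")

    @property
    def depth_px(self) -> int:
        return self.image.shape[0]


@dataclass
class ProcConfig:
    """Parameters of the post-processing chain.

    Dispersion coefficients default to ``None``, meaning "read the values the
    simulator recorded in the fringe metadata" — i.e. matched compensation.
    """

    k_grid_points: Optional[int] = None
    interp_method: str = "cubic"
    dispersion_a2: Optional[float] = None
    dispersion_a3: Optional[float] = None
    k0: Optional[float] = None
    log_epsilon: float = 1e-6
    window_mode: str = "from_reference"  # or "fixed"
    fixed_window_db: tuple[float, float] = (-40.0, 0.0)
    window_floor_percentile: float = 5.0
    background_mode: str = "per_ascan"
    hann_apodization: bool = False


def k_linearize(
    ds: BackgroundFreeFringe, lambda_axis_nm: np.ndarray | None = None,
    n_points: int | None = None, method: str = "cubic",
) -> tuple[np.ndarray, np.ndarray]:
    """Resample spectra onto a uniform wavenumber grid.

    Returns ``(k_grid, values)`` with ``k_grid`` uniform and strictly
    increasing over [min k, max k] and ``values`` of shape
    (n_points, n_ascans) resampled by cubic interpolation.
    """
    lam = np.asarray(
        ds.lambda_axis_nm if lambda_axis_nm is None else lambda_axis_nm, dtype=float
    )
    d = np.diff(lam)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("wavelength axis must be strictly monotonic")
    k = 2 * np.pi / (lam / 1000.0)  # rad/um
    vals = ds.values
    if k[0] > k[-1]:  # wavelength-increasing order means k decreasing
        k = k[::-1]
        vals = vals[::-1]
    n = n_points or len(k)
    k_grid = np.linspace(k[0], k[-1], n)
    if method == "cubic":
        f = CubicSpline(k, vals, axis=0)
    elif method == "linear":
        f = interp1d(k, vals, axis=0, kind="linear")
    else:
        raise ValueError(f"unknown interp method {method!r}")
    return k_grid, np.asarray(f(k_grid))


def analytic_signal(values: np.ndarray) -> np.ndarray:
    """Complex analytic spectrum via Hilbert transform along the spectral
    (first) axis."""
    return hilbert(values, axis=0)


def compensate_dispersion(
    kspace: np.ndarray, k_grid: np.ndarray, a2: float, a3: float, k0: float
) -> np.ndarray:
    """Multiply each spectral sample by ``exp(-i [a2 dk^2 + a3 dk^3])``.

    A pure phase factor: the spectral energy sum |.|^2 is preserved exactly.
    """
    dk = np.asarray(k_grid, dtype=float) - k0
    phase = a2 * dk**2 + a3 * dk**3
    return kspace * np.exp(-1j * phase)[:, None]


def axial_pitch_um(k_grid: np.ndarray) -> float:
    """Depth pixel pitch of the FFT of a uniform k grid, in um/px."""
    n = len(k_grid)
    dk = (k_grid[-1] - k_grid[0]) / (n - 1)
    return float(np.pi / (n * dk))


def to_bscan(
    kspace: np.ndarray,
    k_grid: np.ndarray,
    cfg: ProcConfig,
    bit_depth_tag: int,
    reference_window: tuple[float, float] | None = None,
) -> BScan:
    """FFT to depth, keep the positive-depth half, log-compress and window."""
    n = kspace.shape[0]
    depth = np.fft.fft(kspace, axis=0)[: n // 2]
    mag = np.abs(depth)
    log_img = 20.0 * np.log10(mag + cfg.log_epsilon)
    if reference_window is not None:
        lo, hi = reference_window
    elif cfg.window_mode == "fixed":
        lo, hi = cfg.fixed_window_db
    elif cfg.window_mode == "from_reference":
        lo = float(np.percentile(log_img, cfg.window_floor_percentile))
        hi = float(log_img.max())
    else:
        raise ValueError(f"unknown window mode {cfg.window_mode!r}")
    if lo >= hi:
        raise ValueError(f"degenerate display window [{lo}, {hi}]")
    img = np.clip((log_img - lo) / (hi - lo), 0.0, 1.0)
    return BScan(
        image=img,
        axial_pitch_um=axial_pitch_um(k_grid),
        bit_depth_tag=bit_depth_tag,
        display_window_db=(lo, hi),
        meta={"log_epsilon": cfg.log_epsilon},
    )


def _dispersion_params(fringe: SpectralFringe, cfg: ProcConfig):
    a2 = cfg.dispersion_a2 if cfg.dispersion_a2 is not None else fringe.meta.get("dispersion_a2", 0.0)
    a3 = cfg.dispersion_a3 if cfg.dispersion_a3 is not None else fringe.meta.get("dispersion_a3", 0.0)
    if cfg.k0 is not None:
        k0 = cfg.k0
    elif "k0" in fringe.meta:
        k0 = fringe.meta["k0"]
    else:
        lam_um = np.median(fringe.lambda_axis_nm) / 1000.0
        k0 = 2 * np.pi / lam_um
    return float(a2), float(a3), float(k0)


def process(
    fringe: SpectralFringe,
    cfg: ProcConfig | None = None,
    reference_window: tuple[float, float] | None = None,
) -> BScan:
    """Full chain: background subtraction -> k-linearization -> analytic
    signal -> dispersion compensation -> FFT/log/window."""
    cfg = cfg or ProcConfig()
    ds = subtract_background(fringe, mode=cfg.background_mode)
    k_grid, vals = k_linearize(
        ds, n_points=cfg.k_grid_points, method=cfg.interp_method
    )
    # align the representation scale: an N-bit fringe is the 12-bit one
    # floor-divided by 2^(12-N), so its magnitudes sit 20*log10(2^(12-N)) dB
    # lower; undo that known gain so one display window serves all bit depths
    if fringe.bit_depth < 12:
        vals = vals * float(2 ** (12 - fringe.bit_depth))
    if cfg.hann_apodization:
        vals = vals * np.hanning(len(k_grid))[:, None]
    spec = analytic_signal(vals)
    a2, a3, k0 = _dispersion_params(fringe, cfg)
    spec = compensate_dispersion(spec, k_grid, a2, a3, k0)
    return to_bscan(spec, k_grid, cfg, fringe.bit_depth, reference_window)


def reference_window(
    fringe12: SpectralFringe, cfg: ProcConfig | None = None
) -> tuple[float, float]:
    """Display window of a scene's 12-bit image: [5th percentile, max] of its
    log image.  Apply this window to every lower-bit variant of the scene."""
    return process(fringe12, cfg).display_window_db


def resize_image(image: np.ndarray, size: tuple[int, int] | int) -> np.ndarray:
    """Bicubic, antialiased resize to ``size`` (rows, cols), clipped to
    [0, 1] — the geometry used to feed B-scans to the network."""
    if isinstance(size, int):
        size = (size, size)
    out = _sk_resize(
        np.asarray(image, dtype=float), size, order=3, anti_aliasing=True,
        mode="reflect", preserve_range=True,
    )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# B-scan I/O: 16-bit TIFF (analysis precision) + JSON metadata, optional PNG


def write_bscan(b: BScan, path, png: bool = False) -> None:
    """Write a B-scan as 16-bit TIFF plus a JSON metadata sidecar; with
    ``png=True`` also an 8-bit display PNG."""
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.round(b.image * 65535.0).astype(np.uint16))
    meta = {
        "axial_pitch_um": b.axial_pitch_um,
        "bit_depth_tag": b.bit_depth_tag,
        "display_window_db": list(b.display_window_db),
        "meta": b.meta,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta))
    if png:
        import imageio.v3 as iio

        iio.imwrite(path.with_suffix(".png"), np.round(b.image * 255).astype(np.uint8))


def read_bscan(path) -> BScan:
    import json
    from pathlib import Path

    import tifffile

    path = Path(path)
    side = Path(str(path) + ".json")
    if not side.exists():
        raise FileNotFoundError(f"missing B-scan sidecar {side}")
    meta = json.loads(side.read_text())
    img = tifffile.imread(path).astype(float) / 65535.0
    return BScan(
        image=img,
        axial_pitch_um=meta["axial_pitch_um"],
        bit_depth_tag=meta["bit_depth_tag"],
        display_window_db=tuple(meta["display_window_db"]),
        meta=meta.get("meta", {}),
    )
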