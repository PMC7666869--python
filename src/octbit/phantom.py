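"""Synthetic retina-like scenes and their 12-bit SD-OCT spectral fringes.

The generator stands in for clinical acquisitions: it builds layered
reflectivity scenes with the hallmarks of a retinal B-scan — a bright inner
limiting membrane (ILM), weakly scattering inner retina, the brightest
retinal pigment epithelium (RPE) band, a textured vascular choroid ending at
the fuzzy choroid–sclera interface (CSI), and vessel projection shadows —
and digitizes the corresponding spectral interferograms the way a 12-bit
line-camera ADC would.

Forward model (per A-scan column, spectral pixel i):

    I(lambda_i) = floor(clip(gain * S(k_i) * [1 + Re sum_z A_z e^{i(2 k_i z + phi_d(k_i))}]
                            + shot + read noise, 0, 4095))

with k_i = 2*pi/lambda_i, source envelope S(k) Gaussian, dispersion phase
phi_d(k) = a2 (k - k0)^2 + a3 (k - k0)^3, and complex scatterer amplitudes
A_z = 2 sqrt(r_z) e^{i theta_z} (specular interfaces: theta = 0; tissue body:
circular-Gaussian speckle).  Spectral sampling is uniform in wavelength, not
wavenumber, so the k-linearization stage downstream is genuinely exercised;
``sample_in_k=True`` switches to a wavenumber-uniform grid for oracle tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .quantize import NATIVE_BITS, NATIVE_MAX, SpectralFringe

PRESETS = ("flat", "curved", "pathological")

# canonical layer stack, shallow to deep
LAYER_ORDER = ("ILM", "IPL", "OPL", "RPE", "CSI")


@dataclass
class RetinalPhantom:
    """Ground-truth layered reflectivity scene with known boundary depths.

    ``boundaries`` maps layer name -> per-column interface depth in um
    (row 0 of the processed image is zero optical path delay; depth increases
    downward).  ``reflectivity`` holds linear interface reflectances in
    [0, 1]; ``body_amplitude`` the mean speckle scattering amplitude of the
    three tissue bands (retina body, choroid, sclera).  ``shadow_mask`` is a
    per-column multiplicative attenuation in (0, 1] applied to every
    scatterer deeper than ``shadow_depth_um`` — the synthetic analogue of
    vessel projection shadows.
    """

    width: int
    axial_range_um: float
    boundaries: dict[str, np.ndarray]
    reflectivity: dict[str, float]
    body_amplitude: dict[str, float] = field(default_factory=dict)
    shadow_mask: np.ndarray | None = None
    shadow_depth_um: float = 0.0
    attenuation_length_um: float = 0.0  # 0 disables depth attenuation
    speckle_seed: int = 0
    preset: str = "custom"

    def __post_init__(self) -> None:
        self.boundaries = {
            k: np.broadcast_to(np.asarray(v, dtype=float), (self.width,)).copy()
            for k, v in self.boundaries.items()
        }
        if self.shadow_mask is None:
            self.shadow_mask = np.ones(self.width)
        self.shadow_mask = np.asarray(self.shadow_mask, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.width < 1:
            raise ValueError("width must be >= 1")
        names = list(self.boundaries)
        for k, v in self.boundaries.items():
            if v.shape != (self.width,):
                raise ValueError(f"boundary {k} has wrong length")
            if np.any(v < 0) or np.any(v >= self.axial_range_um):
                raise ValueError(f"boundary {k} outside [0, axial_range_um)")
        for a, b in zip(names, names[1:]):
            if not np.all(self.boundaries[a] < self.boundaries[b]):
                raise ValueError(f"boundaries {a} and {b} not strictly increasing")
        for k, r in self.reflectivity.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"reflectivity {k}={r} outside [0, 1]")
        if "ILM" in self.reflectivity and "RPE" in self.reflectivity:
            rest = [r for k, r in self.reflectivity.items() if k not in ("ILM", "RPE")]
            lo = min(self.reflectivity["ILM"], self.reflectivity["RPE"])
            if rest and lo < max(rest):
                raise ValueError("ILM and RPE must carry the two largest reflectivities")
        if np.any(self.shadow_mask <= 0) or np.any(self.shadow_mask > 1):
            raise ValueError("shadow_mask values must lie in (0, 1]")

    @property
    def csi_truth_um(self) -> np.ndarray:
        """Per-column ground-truth CSI depth in um."""
        return self.boundaries["CSI"].copy()


@dataclass
class AcquisitionConfig:
    """Spectrometer/ADC model of the simulated SD-OCT system.

    Defaults mimic an 840-nm retinal SD-OCT: 2048 spectral pixels spanning
    80 nm, a Gaussian source of 45 nm FWHM, quadratic/cubic dispersion
    imbalance about the center wavenumber, Poisson shot noise plus Gaussian
    read noise, and a 12-bit ADC.
    """

    n_spectral_pixels: int = 2048
    center_wavelength_nm: float = 840.0
    span_nm: float = 80.0
    bandwidth_nm: float = 45.0
    dispersion_a2: float = 30.0  # rad per (rad/um)^2
    dispersion_a3: float = 120.0  # rad per (rad/um)^3
    source_peak_counts: float = 800.0
    #: ADC counts per photoelectron: shot noise in counts is
    #: sqrt(gain * signal_counts), so a small gain (a deep camera well)
    #: means a clean analog signal whose weak fringes coarse quantization
    #: genuinely destroys rather than dithers through
    camera_gain: float = 1.0
    shot_noise: bool = True
    read_noise_counts: float = 3.0
    noise_seed: int = 0
    sample_in_k: bool = False
    native_bit_depth: int = NATIVE_BITS

    @property
    def lambda_axis_nm(self) -> np.ndarray:
        """Wavelength of each spectral pixel: uniform in lambda by default;
        with ``sample_in_k`` the grid is uniform in wavenumber instead and
        the wavelengths are correspondingly non-uniform (decreasing k order
        maps to increasing lambda)."""
        c, s = self.center_wavelength_nm, self.span_nm
        lo, hi = c - s / 2, c + s / 2
        if self.sample_in_k:
            k_hi, k_lo = 2 * np.pi / (lo / 1000.0), 2 * np.pi / (hi / 1000.0)
            k = np.linspace(k_hi, k_lo, self.n_spectral_pixels)  # decreasing
            return 2 * np.pi / k * 1000.0
        return np.linspace(lo, hi, self.n_spectral_pixels)

    @property
    def k_axis(self) -> np.ndarray:
        """Wavenumber of each spectral pixel in rad/um (decreasing with
        pixel index, since wavelength increases)."""
        lam_um = self.lambda_axis_nm / 1000.0
        return 2 * np.pi / lam_um

    @property
    def k0(self) -> float:
        return 2 * np.pi / (self.center_wavelength_nm / 1000.0)

    @property
    def nyquist_depth_um(self) -> float:
        """Unambiguous single-sided depth range implied by the k sampling."""
        k = np.sort(self.k_axis)
        dk = (k[-1] - k[0]) / (len(k) - 1)
        return np.pi / (2 * dk)

    def source_envelope(self) -> np.ndarray:
        """Gaussian source power spectral density S(k), peak-normalized."""
        lam0_um = self.center_wavelength_nm / 1000.0
        sigma_lam_um = (self.bandwidth_nm / 1000.0) / 2.3548200450309493
        sigma_k = 2 * np.pi * sigma_lam_um / lam0_um**2
        return np.exp(-0.5 * ((self.k_axis - self.k0) / sigma_k) ** 2)


def _smooth_field(rng: np.random.Generator, n: int, corr: int, amp: float) -> np.ndarray:
    """Smooth zero-mean 1-D random field via moving-average of white noise."""
    w = rng.standard_normal(n + 2 * corr)
    kern = np.hanning(2 * corr + 1)
    kern /= kern.sum()
    f = np.convolve(w, kern, mode="same")[corr : corr + n]
    s = f.std()
    return amp * f / s if s > 0 else np.zeros(n)


def make_phantom(width: int, seed: int, preset: str = "curved") -> RetinalPhantom:
    """Build a deterministic retina-like scene.

    Presets: ``flat`` (all boundaries constant — CSI truth is a constant
    line), ``curved`` (bowl curvature plus smooth choroidal-thickness
    variation), ``pathological`` (curved plus an RPE elevation, emulating a
    pigment-epithelium detachment).
    """
    if width < 8:
        raise ValueError("width must be >= 8")
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    rng = np.random.default_rng([seed, PRESETS.index(preset), width])
    x = np.arange(width, dtype=float)
    u = 2 * x / max(width - 1, 1) - 1  # [-1, 1]

    base = {"ILM": 250.0, "IPL": 340.0, "OPL": 430.0, "RPE": 520.0, "CSI": 700.0}
    bnd = {k: np.full(width, v) for k, v in base.items()}

    if preset in ("curved", "pathological"):
        bowl = 50.0 * u**2 + _smooth_field(rng, width, max(width // 8, 4), 8.0)
        for k in bnd:
            bnd[k] = bnd[k] + bowl
        # choroidal thickness varies smoothly and independently
        bnd["CSI"] = bnd["CSI"] + _smooth_field(rng, width, max(width // 6, 4), 25.0)
    if preset == "pathological":
        c = rng.uniform(0.25, 0.75) * (width - 1)
        w_b = 0.12 * width
        bump = 45.0 * np.exp(-0.5 * ((x - c) / w_b) ** 2)
        bnd["RPE"] = bnd["RPE"] - bump  # RPE lifted toward the vitreous
        bnd["OPL"] = np.minimum(bnd["OPL"], bnd["RPE"] - 10.0)

    # vessel projection shadows: 2-3 vessels, partial attenuation below them
    shadow = np.ones(width)
    n_vessels = int(rng.integers(2, 4))
    for _ in range(n_vessels):
        c = rng.uniform(0.1, 0.9) * (width - 1)
        half = rng.uniform(2.0, 5.0)
        depthf = rng.uniform(0.35, 0.65)
        shadow *= 1.0 - depthf * np.exp(-0.5 * ((x - c) / half) ** 2)

    # the CSI carries no specular interface: it is a scattering-contrast
    # boundary (vascular choroid above, weakly scattering sclera below), so
    # its visibility is SNR-limited — the property the downstream
    # segmentation probe relies on
    refl = {"ILM": 0.010, "IPL": 0.0012, "OPL": 0.0012, "RPE": 0.014, "CSI": 0.0}
    body = {"retina": 0.010, "choroid": 0.045, "sclera": 0.009}
    return RetinalPhantom(
        width=width,
        axial_range_um=1100.0,
        boundaries=bnd,
        reflectivity=refl,
        body_amplitude=body,
        shadow_mask=shadow,
        shadow_depth_um=float(np.median(bnd["IPL"])),
        attenuation_length_um=400.0,
        speckle_seed=int(np.random.default_rng([seed, 7919]).integers(2**31 - 1)),
        preset=preset,
    )


def point_phantom(
    depths_um, reflectivities, width: int = 4, axial_range_um: float = 1100.0
) -> RetinalPhantom:
    """Phantom of K discrete specular reflectors and no tissue body.

    The workhorse of the physics oracle tests: a noiseless acquisition of a
    point phantom must produce A-scan peaks at exactly these depths.
    """
    depths = np.atleast_1d(np.asarray(depths_um, dtype=float))
    refl = np.atleast_1d(np.asarray(reflectivities, dtype=float))
    if depths.shape != refl.shape:
        raise ValueError("depths and reflectivities must have equal length")
    order = np.argsort(depths)
    bnd = {f"L{i}": np.full(width, depths[j]) for i, j in enumerate(order)}
    r = {f"L{i}": float(refl[j]) for i, j in enumerate(order)}
    return RetinalPhantom(
        width=width,
        axial_range_um=axial_range_um,
        boundaries=bnd,
        reflectivity=r,
        body_amplitude={},
        preset="points",
    )


def _scatterers(phantom: RetinalPhantom):
    """Assemble per-column scatterer depths (um) and complex amplitudes.

    Returns (depths, amps) of shape (Z, width); zero-amplitude padding where
    a column has fewer scatterers.
    """
    rng = np.random.default_rng(phantom.speckle_seed)
    w = phantom.width
    cols_d: list[list[float]] = [[] for _ in range(w)]
    cols_a: list[list[complex]] = [[] for _ in range(w)]
    ilm = phantom.boundaries.get("ILM")

    def add(col, depth, amp):
        if phantom.shadow_mask is not None and depth > phantom.shadow_depth_um:
            amp = amp * phantom.shadow_mask[col]
        # single-pass Beer–Lambert attenuation of the probe light through the
        # tissue above: deeper structures (the choroid, the CSI) return less
        # light — the reason their visibility is SNR-limited
        if phantom.attenuation_length_um > 0 and ilm is not None:
            path = max(depth - ilm[col], 0.0)
            amp = amp * np.exp(-path / phantom.attenuation_length_um)
        cols_d[col].append(depth)
        cols_a[col].append(amp)

    for name, dep in phantom.boundaries.items():
        r = phantom.reflectivity.get(name, 0.0)
        a = 2.0 * np.sqrt(r)
        for c in range(w):
            add(c, dep[c], a)

    spacing = 9.0  # um between body scatterers; sub-speckle grain
    regions = []
    if phantom.body_amplitude:
        b = phantom.boundaries
        if "ILM" in b and "RPE" in b:
            regions.append(("retina", b["ILM"] + 6, b["RPE"] - 6))
        if "RPE" in b and "CSI" in b:
            regions.append(("choroid", b["RPE"] + 6, b["CSI"] - 3))
        if "CSI" in b:
            top = b["CSI"] + 3
            regions.append(("sclera", top, np.minimum(top + 150, phantom.axial_range_um - 10)))
    for rname, top, bot in regions:
        amp0 = phantom.body_amplitude.get(rname, 0.0)
        if amp0 <= 0:
            continue
        # choroid vascular texture: lognormal-ish smooth modulation per column
        if rname == "choroid":
            tex = np.exp(_smooth_field(rng, w, max(w // 16, 3), 0.7))
        else:
            tex = np.ones(w)
        for c in range(w):
            n_s = max(int((bot[c] - top[c]) / spacing), 1)
            z = top[c] + (bot[c] - top[c]) * rng.random(n_s)
            ph = rng.standard_normal(n_s) + 1j * rng.standard_normal(n_s)
            a = amp0 * tex[c] * ph / np.sqrt(2.0)
            for zi, ai in zip(z, a):
                add(c, float(zi), complex(ai))

    zmax = max((len(d) for d in cols_d), default=0)
    depths = np.zeros((max(zmax, 1), w))
    amps = np.zeros((max(zmax, 1), w), dtype=complex)
    for c in range(w):
        depths[: len(cols_d[c]), c] = cols_d[c]
        amps[: len(cols_a[c]), c] = cols_a[c]
    return depths, amps


def synthesize_fringes(
    phantom: RetinalPhantom, acq: AcquisitionConfig
) -> SpectralFringe:
    """Simulate the digitized 12-bit spectral interferogram of a phantom."""
    k = acq.k_axis
    depths, amps = _scatterers(phantom)
    if depths.size and float(depths.max()) >= acq.nyquist_depth_um:
        raise ValueError(
            f"phantom depth {depths.max():.1f} um exceeds the unambiguous "
            f"axial range {acq.nyquist_depth_um:.1f} um (aliasing)"
        )
    phi_d = acq.dispersion_a2 * (k - acq.k0) ** 2 + acq.dispersion_a3 * (k - acq.k0) ** 3
    # E[k, col] = sum_z A_z exp(i 2 k z); batched over manageable column chunks
    n_k, w = len(k), phantom.width
    E = np.empty((n_k, w), dtype=complex)
    chunk = max(1, int(4e6 // (n_k * max(depths.shape[0], 1))))
    for c0 in range(0, w, chunk):
        d = depths[:, c0 : c0 + chunk]
        a = amps[:, c0 : c0 + chunk]
        phase = 2.0 * k[:, None, None] * d[None, :, :]
        E[:, c0 : c0 + chunk] = np.einsum("kzc,zc->kc", np.exp(1j * phase), a)
    S = acq.source_envelope()
    signal = acq.source_peak_counts * S[:, None] * (
        1.0 + np.real(np.exp(1j * phi_d)[:, None] * E)
    )
    signal = np.clip(signal, 0.0, None)
    rng = np.random.default_rng(acq.noise_seed)
    if acq.shot_noise:
        g = acq.camera_gain
        signal = rng.poisson(signal / g).astype(float) * g
    if acq.read_noise_counts > 0:
        signal = signal + rng.normal(0.0, acq.read_noise_counts, signal.shape)
    samples = np.clip(np.floor(signal), 0, NATIVE_MAX).astype(np.int32)
    return SpectralFringe(
        samples=samples,
        bit_depth=acq.native_bit_depth,
        lambda_axis_nm=acq.lambda_axis_nm,
        provenance=f"synthetic:{phantom.preset}",
        meta={
            "dispersion_a2": acq.dispersion_a2,
            "dispersion_a3": acq.dispersion_a3,
            "k0": acq.k0,
            "sample_in_k": acq.sample_in_k,
            "noise_seed": acq.noise_seed,
        },
    )


# ---------------------------------------------------------------------------
# fringe I/O: 16-bit TIFF + JSON sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_fringe(fringe: SpectralFringe, path) -> None:
    """Write a fringe as 16-bit grayscale TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, fringe.samples.astype(np.uint16))
    side = {
        "bit_depth": fringe.bit_depth,
        "lambda_axis_nm": fringe.lambda_axis_nm.tolist(),
        "provenance": fringe.provenance,
        "meta": fringe.meta,
    }
    _sidecar_path(path).write_text(json.dumps(side))


def read_fringe(path) -> SpectralFringe:
    """Read a fringe written by :func:`write_fringe`; validates the samples
    against the declared bit depth."""
    path = Path(path)
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar metadata {sc}")
    side = json.loads(sc.read_text())
    samples = tifffile.imread(path).astype(np.int32)
    return SpectralFringe(
        samples=samples,
        bit_depth=int(side["bit_depth"]),
        lambda_axis_nm=np.asarray(side["lambda_axis_nm"], dtype=float),
        provenance=side.get("provenance", ""),
        meta=side.get("meta", {}),
    )


def write_phantom_truth(phantom: RetinalPhantom, path) -> None:
    """Persist per-column boundary depths (um) as JSON ground truth."""
    Path(path).write_text(
        json.dumps(
            {
                "width": phantom.width,
                "axial_range_um": phantom.axial_range_um,
                "preset": phantom.preset,
                "boundaries_um": {k: v.tolist() for k, v in phantom.boundaries.items()},
            }
        )
    )


def read_phantom_truth(path) -> dict:
    return json.loads(Path(path).read_text())
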