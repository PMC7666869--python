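"""Bit-depth reduction of raw spectral fringes and background subtraction.

An SD-OCT line camera digitizes each spectrum to ``N`` bits; lowering ``N``
coarsens the intensity grid to ``2**N`` levels and is the degradation this
package studies.  Re-quantization of native 12-bit data to ``N`` bits is

    I' = floor(I * 2**N / 2**12)

which for integer ``I`` is exactly the right-shift ``I >> (12 - N)``.  The DC
background (source spectrum) is then removed per A-scan by subtracting the
spectral mean, ``DS_j = I'_j - ave(I'_j)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NATIVE_BITS = 12
#: The native ADC full scale: integers in [0, 4095].
NATIVE_MAX = 2**NATIVE_BITS - 1


@dataclass
class SpectralFringe:
    """A 2-D integer spectral interferogram (spectral pixel x A-scan).

    Attributes
    ----------
    samples : ndarray of integers, shape (n_spectral, n_ascans)
        Digitized camera counts, each in ``[0, 2**bit_depth - 1]``.
    bit_depth : int
        ADC bit depth ``N`` of the samples, in ``[1, 16]``.
    lambda_axis_nm : ndarray, shape (n_spectral,)
        Wavelength of each spectral pixel in nm, strictly monotonic.
    provenance : str
        Free-text tag describing how the fringe was produced.
    """

    samples: np.ndarray
    bit_depth: int
    lambda_axis_nm: np.ndarray
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        self.lambda_axis_nm = np.asarray(self.lambda_axis_nm, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (spectral pixel x A-scan)")
        if not np.issubdtype(self.samples.dtype, np.integer):
            raise ValueError("fringe samples must be integers")
        if not 1 <= self.bit_depth <= 16:
            raise ValueError(f"bit_depth {self.bit_depth} outside [1, 16]")
        hi = 2**self.bit_depth - 1
        smin, smax = int(self.samples.min()), int(self.samples.max())
        if smin < 0 or smax > hi:
            raise ValueError(
                f"samples [{smin}, {smax}] exceed {self.bit_depth}-bit range [0, {hi}]"
            )
        lam = self.lambda_axis_nm
        if lam.shape != (self.samples.shape[0],):
            raise ValueError("lambda_axis_nm length must equal the spectral dimension")
        d = np.diff(lam)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("lambda_axis_nm must be strictly monotonic")

    @property
    def n_spectral(self) -> int:
        return self.samples.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.samples.shape[1]


@dataclass
class BackgroundFreeFringe:
    """Background-subtracted fringe: real values, zero mean along each A-scan."""

    values: np.ndarray
    source_bit_depth: int
    lambda_axis_nm: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lambda_axis_nm = np.asarray(self.lambda_axis_nm, dtype=float)


def quantize_fringe(fringe: SpectralFringe, n_bits: int) -> SpectralFringe:
    """Re-quantize a native 12-bit fringe to ``n_bits`` by floor scaling.

    Implements ``I' = floor(I * 2**N / 2**12)`` in exact integer arithmetic
    (equivalently ``I >> (12 - N)`` for N <= 12).

    Parameters
    ----------
    fringe : SpectralFringe
        Must have ``bit_depth == 12``.
    n_bits : int
        Target bit depth, in ``[1, 12]``.
    """
    if not 1 <= n_bits <= NATIVE_BITS:
        raise ValueError(f"target bit depth {n_bits} outside [1, {NATIVE_BITS}]")
    if fringe.bit_depth != NATIVE_BITS:
        raise ValueError(
            f"quantize_fringe expects native {NATIVE_BITS}-bit input, "
            f"got {fringe.bit_depth}-bit"
        )
    fringe.validate()
    shifted = fringe.samples.astype(np.int64) >> (NATIVE_BITS - n_bits)
    return replace(
        fringe,
        samples=shifted,
        bit_depth=n_bits,
        provenance=f"{fringe.provenance}|quantized:{n_bits}bit".lstrip("|"),
    )


def subtract_background(
    fringe: SpectralFringe, mode: str = "per_ascan"
) -> BackgroundFreeFringe:
    """Remove the DC source spectrum: ``DS_j = I'_j - ave(I'_j)``.

    ``mode='per_ascan'`` (default) subtracts each A-scan's own spectral mean,
    so every column of the result sums to zero.  ``mode='mean_fringe'``
    subtracts the spectrum averaged across A-scans instead, a common
    instrument-side estimate of the reference-arm background.
    """
    if fringe.samples.size == 0:
        raise ValueError("empty fringe")
    if fringe.samples.shape[0] < 2:
        raise ValueError("need at least 2 spectral samples per A-scan")
    vals = fringe.samples.astype(float)
    if mode == "per_ascan":
        ds = vals - vals.mean(axis=0, keepdims=True)
    elif mode == "mean_fringe":
        ds = vals - vals.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    return BackgroundFreeFringe(
        values=ds,
        source_bit_depth=fringe.bit_depth,
        lambda_axis_nm=fringe.lambda_axis_nm,
    )
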