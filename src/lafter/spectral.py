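"""Fourier-domain machinery: transforms, shells, Butterworth responses, FSC.

All spatial frequencies are expressed in cycles/voxel, so Nyquist is 0.5
and a "resolution of d voxels" corresponds to frequency 1/d.  Transforms
are real-to-complex (Hermitian); shell sums carry multiplicity weights so
that statistics match the full-transform definition.

Shells are one Fourier voxel wide (1/L cycles/voxel with L the smallest
grid dimension), with each value assigned to the shell-centre frequency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.fft

from .errors import LafterError
from .volume_io import Volume

__all__ = [
    "BandSpec",
    "ShellCurve",
    "NYQUIST",
    "frequency_grid",
    "hermitian_multiplicity",
    "bandpass_weights",
    "lowpass_weights",
    "apply_fourier_weights",
    "compute_fsc",
    "shell_power",
    "fourier_upsample",
]

logger = logging.getLogger(__name__)

#: Highest representable spatial frequency, cycles/voxel.
NYQUIST = 0.5

# Tiny tolerance on band-edge comparisons so that cutoffs computed by
# accumulation (l + k*step) still count as reaching Nyquist exactly.
_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class BandSpec:
    """One resolution band: low and high cutoff frequencies (cycles/voxel)."""

    l: float
    h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.l < self.h <= NYQUIST + _EDGE_TOL):
            raise LafterError(
                f"invalid band: need 0 <= l < h <= {NYQUIST}, got l={self.l}, h={self.h}"
            )

    @property
    def width(self) -> float:
        return self.h - self.l


@dataclass
class ShellCurve:
    """A scalar quantity sampled on ascending frequency shells.

    ``label`` records the semantics (``FSC``, ``Cref``, ``xFSC`` ...).
    """

    freqs: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.freqs.shape != self.values.shape:
            raise LafterError("freqs and values must have the same length")
        if self.freqs.size and (
            np.any(np.diff(self.freqs) <= 0)
            or self.freqs[0] <= 0
            or self.freqs[-1] > NYQUIST + _EDGE_TOL
        ):
            raise LafterError("freqs must be strictly increasing within (0, 0.5]")

    def __len__(self) -> int:
        return self.freqs.size

    def to_tsv(self, path: str | Path) -> None:
        """Write as a two-column TSV (frequency, value)."""
        header = f"frequency\t{self.label or 'value'}"
        np.savetxt(
            path,
            np.column_stack([self.freqs, self.values]),
            delimiter="\t",
            header=header,
            comments="",
            fmt="%.6f",
        )


def frequency_grid(shape: tuple[int, int, int]) -> np.ndarray:
    """Radial spatial frequency |k| (cycles/voxel) on the rfftn layout."""
    fz = np.fft.fftfreq(shape[0])[:, None, None]
    fy = np.fft.fftfreq(shape[1])[None, :, None]
    fx = np.fft.rfftfreq(shape[2])[None, None, :]
    return np.sqrt(fz * fz + fy * fy + fx * fx)


def hermitian_multiplicity(shape: tuple[int, int, int]) -> np.ndarray:
    """Multiplicity of each rfftn coefficient in the full transform.

    Coefficients on the kx = 0 plane (and the kx = Nyquist plane for even
    grids) appear once; all others represent a conjugate pair.
    """
    n2 = shape[2]
    m = np.full(n2 // 2 + 1, 2.0)
    m[0] = 1.0
    if n2 % 2 == 0:
        m[-1] = 1.0
    return np.broadcast_to(m[None, None, :], (shape[0], shape[1], n2 // 2 + 1))


def _butterworth_lowpass(r: np.ndarray, h: float) -> np.ndarray:
    # |H|^2 of an order-8 Butterworth: 1 / (1 + (r/h)^16).
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + (r / h) ** 16)


def lowpass_weights(shape: tuple[int, int, int], h: float) -> np.ndarray:
    """Eighth-order Butterworth low-pass response on the rfftn grid.

    The response is 1/(1 + (r/h)^16): unity at DC, one half at the cutoff,
    monotonically decreasing in r.
    """
    if not (0.0 < h <= NYQUIST + _EDGE_TOL):
        raise LafterError(f"cutoff must lie in (0, {NYQUIST}], got {h}")
    return _butterworth_lowpass(frequency_grid(shape), h)


def bandpass_weights(shape: tuple[int, int, int], band: BandSpec) -> np.ndarray:
    """Eighth-order Butterworth band-pass response on the rfftn grid.

    Built as the difference of two low-passes, 1/(1+(r/h)^16) −
    1/(1+(r/l)^16), which telescopes: responses of contiguous bands sum to
    the single low-pass at the top cutoff, so re-summing band-passed
    volumes needs no further scaling.  ``l = 0`` degenerates to a pure
    low-pass.
    """
    r = frequency_grid(shape)
    w = _butterworth_lowpass(r, band.h)
    if band.l > 0.0:
        w = w - _butterworth_lowpass(r, band.l)
    return w


def apply_fourier_weights(vol: Volume, weights: np.ndarray) -> Volume:
    """Multiply a volume's Fourier transform by a real weight grid."""
    if not np.all(np.isfinite(vol.data)):
        raise LafterError("volume contains non-finite values")
    ft = scipy.fft.rfftn(vol.data.astype(np.float64))
    if weights.shape != ft.shape:
        raise LafterError(
            f"weight grid shape {weights.shape} does not match transform {ft.shape}"
        )
    out = scipy.fft.irfftn(ft * weights, s=vol.data.shape)
    return vol.with_data(out)


def _shell_index(shape: tuple[int, int, int]) -> tuple[np.ndarray, int]:
    """Nearest-integer shell index of every rfftn coefficient.

    Shell i is centred on frequency i/L, L = min(shape); shells past
    Nyquist (corner frequencies) are retained for power bookkeeping but
    excluded from FSC curves.
    """
    L = min(shape)
    idx = np.rint(frequency_grid(shape) * L).astype(np.intp)
    return idx, L


def shell_power(ft: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Total |F|^2 per shell (full-transform convention), all shells."""
    idx, _ = _shell_index(shape)
    mult = hermitian_multiplicity(shape)
    p = (ft.real**2 + ft.imag**2) * mult
    return np.bincount(idx.ravel(), weights=p.ravel())


def compute_fsc(
    vol_a: Volume | np.ndarray,
    vol_b: Volume | np.ndarray,
    shell_width: float | None = None,
    label: str = "FSC",
) -> ShellCurve:
    """Fourier shell correlation between two equally shaped volumes.

    Per shell: Re(sum F_a F_b*) / sqrt(sum |F_a|^2 · sum |F_b|^2).  A shell
    with zero power in either input is reported as 0 with a warning.
    ``shell_width`` defaults to one Fourier voxel and must currently be a
    multiple of it.
    """
    a = vol_a.data if isinstance(vol_a, Volume) else np.asarray(vol_a)
    b = vol_b.data if isinstance(vol_b, Volume) else np.asarray(vol_b)
    if a.shape != b.shape:
        raise LafterError(f"shape mismatch: {a.shape} vs {b.shape}")
    idx, L = _shell_index(a.shape)
    if shell_width is not None:
        step = max(1, int(round(shell_width * L)))
    else:
        step = 1
    fa = scipy.fft.rfftn(a.astype(np.float64))
    fb = scipy.fft.rfftn(b.astype(np.float64))
    mult = hermitian_multiplicity(a.shape)
    sidx = (idx // step).ravel()
    cross = np.bincount(sidx, weights=((fa * fb.conj()).real * mult).ravel())
    pa = np.bincount(sidx, weights=((fa.real**2 + fa.imag**2) * mult).ravel())
    pb = np.bincount(sidx, weights=((fb.real**2 + fb.imag**2) * mult).ravel())
    nshells = (L // 2) // step
    shells = np.arange(1, nshells + 1)
    cross, pa, pb = cross[shells], pa[shells], pb[shells]
    denom = np.sqrt(pa * pb)
    ok = denom > 0
    if not np.all(ok):
        logger.warning(
            "FSC: %d of %d shells carry no power in one input; reported as 0",
            int((~ok).sum()),
            nshells,
        )
    values = np.zeros(nshells)
    np.divide(cross, denom, out=values, where=ok)
    values = np.clip(values, -1.0, 1.0)
    freqs = shells * step / L
    return ShellCurve(freqs, values, label)


def fourier_upsample(vol: Volume, factor: int = 2) -> Volume:
    """Zero-padded Fourier interpolation onto a ``factor``-times finer grid.

    The physical extent is unchanged: voxel size shrinks by ``factor``.
    Used only to write a smooth final map; metrics stay at native sampling.
    """
    if factor < 1:
        raise LafterError("upsampling factor must be >= 1")
    if factor == 1:
        return vol
    shape = vol.data.shape
    new_shape = tuple(s * factor for s in shape)
    ft = scipy.fft.fftn(vol.data.astype(np.float64))
    # Shift the spectrum to centred order, zero-pad, shift back.
    centred = np.fft.fftshift(ft)
    pads = [((ns - s + 1) // 2, (ns - s) // 2) for s, ns in zip(shape, new_shape)]
    padded = np.pad(centred, pads)
    big = np.fft.ifftshift(padded)
    out = scipy.fft.ifftn(big).real * factor**3
    return Volume(
        out.astype(np.float32),
        tuple(v / factor for v in vol.voxel_size),
        vol.origin,
    )
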