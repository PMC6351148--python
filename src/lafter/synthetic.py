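"""Synthetic half-map experiments with controllable resolution and FSC.

A noiseless phantom density is band-limited to a chosen resolution (flat,
or graded along an axis) and split into two half-maps by adding
independent Fourier-space Gaussian noise, coloured per frequency shell so
the expected half-set FSC is flat at a chosen target.  Summing the halves
emulates a full reconstruction; the truncated noiseless map is kept as
ground truth, which is what makes the evaluation metrics checkable.

Noise power is calibrated against the *untruncated* phantom spectrum, so
the noise-to-signal ratio seen below the resolution cutoff is maintained
beyond it: past the cutoff there is noise but no signal, the regime a real
reconstruction terminates in.

Phantom geometry depends only on the phantom name, never on the noise
seed: different seeds give different half-maps but an identical truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.fft
from scipy.interpolate import CubicSpline

from .errors import LafterError
from .spectral import _shell_index, hermitian_multiplicity, lowpass_weights
from .volume_io import MaskedRegion, Volume

__all__ = [
    "SyntheticSpec",
    "make_phantom",
    "truncate_resolution",
    "add_noise_for_fsc",
    "make_experiment",
]

logger = logging.getLogger(__name__)

#: Densities below this fraction of the maximum are zeroed, giving the
#: phantom compact support inside the box.
_SUPPORT_FLOOR = 1e-3


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic half-map experiment.

    ``truncation_resolution`` is in voxels (>= 2, Nyquist); a pair
    ``(r_start, r_end)`` requests a resolution gradient along axis 0.
    ``target_fsc`` is the flat half-set FSC the noise is calibrated to.
    """

    shape: int | tuple[int, int, int] = 64
    truncation_resolution: float | tuple[float, float] = 4.0
    target_fsc: float = 0.5
    seed: int = 0
    phantom: str = "curve"

    def __post_init__(self) -> None:
        if not (0.0 < self.target_fsc < 1.0):
            raise LafterError("target_fsc must lie in (0, 1)")
        res = self.truncation_resolution
        rmin = min(res) if isinstance(res, tuple) else res
        if rmin < 2.0:
            raise LafterError(
                f"truncation resolution must be >= 2 voxels (Nyquist), got {res}"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        s = self.shape
        return (s, s, s) if isinstance(s, int) else tuple(s)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _curve_phantom(shape: tuple[int, int, int], rng: np.random.Generator
                   ) -> np.ndarray:
    """Gaussian beads along a smooth closed random curve, plus broad lobes.

    Gives multi-scale structure: a broad envelope, a tube of ~4-voxel
    features, and bead-to-bead spacing variation at finer scales.
    """
    L = np.array(shape, dtype=float)
    ncontrol = 7
    t = np.linspace(0, 1, ncontrol + 1)
    ctrl = rng.uniform(0.32, 0.68, size=(ncontrol, 3)) * L
    ctrl = np.vstack([ctrl, ctrl[:1]])  # close the loop
    spline = CubicSpline(t, ctrl, bc_type="periodic")
    pts = spline(np.linspace(0, 1, 260, endpoint=False))
    widths = 1.8 + 1.4 * np.sin(np.linspace(0, 6 * np.pi, len(pts))) ** 2
    amps = 0.7 + 0.3 * np.cos(np.linspace(0, 10 * np.pi, len(pts)))

    out = np.zeros(shape)
    zz, yy, xx = np.indices(shape)
    # Broad lobes for low-resolution structure.
    for centre_frac, sigma_frac in ((0.42, 0.10), (0.58, 0.085)):
        c = L * centre_frac
        s = float(L.min() * sigma_frac)
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        out += 0.35 * np.exp(-d2 / (2 * s * s))
    # Beads, each evaluated only inside a local cube.
    for (pz, py, px), w, a in zip(pts, widths, amps):
        r = int(np.ceil(3.5 * w))
        z0, z1 = max(int(pz) - r, 0), min(int(pz) + r + 1, shape[0])
        y0, y1 = max(int(py) - r, 0), min(int(py) + r + 1, shape[1])
        x0, x1 = max(int(px) - r, 0), min(int(px) + r + 1, shape[2])
        lz, ly, lx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1),
            indexing="ij",
        )
        d2 = (lz - pz) ** 2 + (ly - py) ** 2 + (lx - px) ** 2
        out[z0:z1, y0:y1, x0:x1] += a * np.exp(-d2 / (2 * w * w))
    return out


def _helix_phantom(shape: tuple[int, int, int], rng: np.random.Generator
                   ) -> np.ndarray:
    """A helical tube around a central rod (deterministic geometry)."""
    del rng  # geometry is fixed
    out = np.zeros(shape)
    L = np.array(shape, dtype=float)
    npts = 220
    s = np.linspace(0, 1, npts)
    radius = 0.14 * L.min()
    pts = np.column_stack([
        L[0] * (0.27 + 0.46 * s),
        L[1] / 2 + radius * np.cos(5 * np.pi * s),
        L[2] / 2 + radius * np.sin(5 * np.pi * s),
    ])
    rod = np.column_stack([
        L[0] * (0.27 + 0.46 * s), np.full(npts, L[1] / 2), np.full(npts, L[2] / 2)
    ])
    for track, w, a in ((pts, 2.2, 1.0), (rod, 3.0, 0.6)):
        for pz, py, px in track:
            r = int(np.ceil(3.5 * w))
            z0, z1 = max(int(pz) - r, 0), min(int(pz) + r + 1, shape[0])
            y0, y1 = max(int(py) - r, 0), min(int(py) + r + 1, shape[1])
            x0, x1 = max(int(px) - r, 0), min(int(px) + r + 1, shape[2])
            lz, ly, lx = np.meshgrid(
                np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1),
                indexing="ij",
            )
            d2 = (lz - pz) ** 2 + (ly - py) ** 2 + (lx - px) ** 2
            out[z0:z1, y0:y1, x0:x1] += a * np.exp(-d2 / (2 * w * w))
    return out


_PHANTOMS = {"curve": _curve_phantom, "helix": _helix_phantom}


def make_phantom(spec: SyntheticSpec) -> Volume:
    """Build the named noiseless phantom density.

    Non-negative, compactly supported well inside the box, with maximum 1.
    Deterministic given the spec; the geometry RNG is seeded from the
    phantom name only.
    """
    try:
        builder = _PHANTOMS[spec.phantom]
    except KeyError:
        raise LafterError(
            f"unknown phantom {spec.phantom!r}; available: {sorted(_PHANTOMS)}"
        ) from None
    geometry_seed = int.from_bytes(spec.phantom.encode(), "little") % (2**31)
    rng = np.random.default_rng(geometry_seed)
    data = builder(spec.grid_shape, rng)
    data /= data.max()
    data[data < _SUPPORT_FLOOR] = 0.0
    return Volume(data.astype(np.float32))


def truncate_resolution(
    vol: Volume, resolution: float | tuple[float, float]
) -> Volume:
    """Band-limit a volume to a resolution given in voxels.

    A scalar applies an eighth-order Butterworth low-pass at frequency
    1/resolution.  A pair ``(r_start, r_end)`` grades the cutoff along
    axis 0 by blending 12 log-spaced globally low-passed copies per slice
    (spatially varying filtering is not separable in Fourier space; the
    blend is a close approximation at this grid size).
    """
    shape = vol.data.shape
    if not isinstance(resolution, tuple):
        if resolution < 2.0:
            raise LafterError("resolution must be >= 2 voxels")
        w = lowpass_weights(shape, min(1.0 / resolution, 0.5))
        out = scipy.fft.irfftn(
            scipy.fft.rfftn(vol.data.astype(np.float64)) * w, s=shape
        )
        return vol.with_data(out)
    r0, r1 = max(resolution[0], 2.0), max(resolution[1], 2.0)
    levels = np.geomspace(min(r0, r1), max(r0, r1), 12)  # ascending for interp
    ft = scipy.fft.rfftn(vol.data.astype(np.float64))
    stack = np.stack([
        scipy.fft.irfftn(ft * lowpass_weights(shape, min(1.0 / rv, 0.5)), s=shape)
        for rv in levels
    ])
    # Per-slice resolution interpolates log-linearly along axis 0.
    slice_res = np.geomspace(r0, r1, shape[0])
    pos = np.interp(np.log(slice_res), np.log(levels), np.arange(len(levels)))
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, len(levels) - 1)
    frac = pos - lo
    out = np.empty(shape)
    for z in range(shape[0]):
        out[z] = (1 - frac[z]) * stack[lo[z], z] + frac[z] * stack[hi[z], z]
    return vol.with_data(out)


def add_noise_for_fsc(
    vol: Volume,
    target_fsc: float,
    seed: int | np.random.SeedSequence,
    reference: Volume | None = None,
) -> tuple[Volume, Volume]:
    """Split a noiseless volume into two half-maps at a target flat FSC.

    Independent Hermitian-symmetric complex Gaussian noise is added to the
    Fourier transform of ``vol`` for each half.  Per shell, the noise
    power is S * (1/FSC - 1) where S is the shell power of ``reference``
    (default: ``vol`` itself), which makes the expected half-set FSC
    S/(S+N) = ``target_fsc`` in every shell carrying signal.  Shells where
    the reference has no power get no noise.

    The noise is realised by colouring real-space white Gaussian noise, so
    Hermitian symmetry — hence reality of the halves — is exact.
    """
    if not (0.0 < target_fsc < 1.0):
        raise LafterError("target_fsc must lie in (0, 1)")
    if reference is None:
        reference = vol
    shape = vol.data.shape
    idx, _ = _shell_index(shape)
    mult = hermitian_multiplicity(shape)
    ref_ft = scipy.fft.rfftn(reference.data.astype(np.float64))
    ref_power = np.bincount(
        idx.ravel(), weights=((np.abs(ref_ft) ** 2) * mult).ravel()
    )
    noise_power = ref_power * (1.0 / target_fsc - 1.0)
    if not np.all(ref_power[1:] > 0):
        logger.info("shells without signal get no noise (%d shells)",
                    int((ref_power[1:] == 0).sum()))

    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    halves = []
    F = scipy.fft.rfftn(vol.data.astype(np.float64))
    for child in ss.spawn(2):
        rng = np.random.default_rng(child)
        white = rng.standard_normal(shape)
        W = scipy.fft.rfftn(white)
        white_power = np.bincount(
            idx.ravel(), weights=((np.abs(W) ** 2) * mult).ravel()
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.sqrt(
                np.divide(noise_power, white_power,
                          out=np.zeros_like(noise_power),
                          where=white_power > 0)
            )
        noisy = scipy.fft.irfftn(F + W * scale[idx], s=shape)
        halves.append(vol.with_data(noisy))
    return halves[0], halves[1]


def _soft_box_mask(support: np.ndarray, margin: int = 2,
                   edge: int = 5) -> np.ndarray:
    """A soft-edged box enclosing all support voxels.

    Separable cosine-tapered window: 1 over the support bounding box plus
    ``margin``, falling to 0 over ``edge`` voxels.  The whole taper is kept
    inside the grid where possible — a mask truncated hard at the box faces
    leaks spectrally and deflates every masked FSC.
    """
    shape = support.shape
    profiles = []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        hit = np.nonzero(support.any(axis=other))[0]
        lo = (int(hit[0]) if hit.size else shape[axis] // 4) - margin
        hi = (int(hit[-1]) if hit.size else 3 * shape[axis] // 4) + margin
        lo = max(lo, 0)
        hi = min(hi, shape[axis] - 1)
        x = np.arange(shape[axis], dtype=float)
        dist = np.maximum(lo - x, x - hi)
        ramp = np.clip(dist / edge, 0.0, 1.0)
        profiles.append(0.5 * (1.0 + np.cos(np.pi * ramp)))
    return profiles[0][:, None, None] * profiles[1][None, :, None] \
        * profiles[2][None, None, :]


def make_experiment(
    spec: SyntheticSpec,
) -> tuple[Volume, Volume, MaskedRegion, Volume]:
    """Generate (half1, half2, mask, truth) for one synthetic experiment.

    Pipeline: phantom → resolution truncation → per-shell noise at the
    target FSC (calibrated against the untruncated phantom).  The mask is
    a soft-edged box enclosing the phantom support; the truth is the
    truncated noiseless map.
    """
    phantom = make_phantom(spec)
    truth = truncate_resolution(phantom, spec.truncation_resolution)
    half1, half2 = add_noise_for_fsc(
        truth, spec.target_fsc, spec.seed, reference=phantom
    )
    mask_data = _soft_box_mask(phantom.data > 0)
    mask = MaskedRegion(mask_data.astype(np.float32))
    return half1, half2, mask, truth
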