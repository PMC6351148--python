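"""MRC volume input/output and input validation.

Density maps are exchanged in the MRC2014 format.  Files are always written
in mode 2 (32-bit float); modes 0, 1, 2 and 6 are accepted on read, with
integer data promoted to float.  Grid data is stored in the canonical
(slow, medium, fast) axis order; files whose axis mapping differs are
reordered on read, so all internal operations can remain axis-order
agnostic.

Anisotropic voxel sizes round-trip through read/write, but the filter
itself rejects them: the radial frequency machinery assumes isotropic
sampling, as is universal for single-particle reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import MapFormatError, MaskError, ValidationError

__all__ = [
    "Volume",
    "MaskedRegion",
    "read_volume",
    "write_volume",
    "read_mask",
    "validate_triplet",
]

#: MRC data modes accepted on read (int8, int16, float32, uint16).
_ACCEPTED_MODES = (0, 1, 2, 6)


@dataclass
class Volume:
    """A 3D scalar density grid with physical metadata.

    Parameters
    ----------
    data
        3D array of density values (arbitrary units).  Stored as float32.
    voxel_size
        Sampling in Angstrom per voxel along each axis (positive).
    origin
        Physical offset (Angstrom) of the first grid point.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise MapFormatError(
                f"volume must be 3-dimensional, got ndim={self.data.ndim}"
            )
        if any(s < 2 for s in self.data.shape):
            raise MapFormatError(
                f"all dimensions must be >= 2, got shape={self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise MapFormatError("volume contains non-finite values")
        vs = tuple(float(v) for v in np.broadcast_to(self.voxel_size, (3,)))
        if any(v <= 0 for v in vs):
            raise MapFormatError(f"voxel size must be positive, got {vs}")
        self.voxel_size = vs
        self.origin = tuple(float(o) for o in np.broadcast_to(self.origin, (3,)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume sharing this volume's metadata."""
        return Volume(data, self.voxel_size, self.origin)


@dataclass
class MaskedRegion:
    """A 0-to-1 map marking the region considered during refinement.

    Noise statistics are only valid inside the refined region.  Voxels with
    value >= 0.5 count as refined; ``n`` is their number and enters the
    noise standard deviation sigma_N = sqrt(N/n).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    indicator: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise MaskError(f"mask must be 3-dimensional, got ndim={self.data.ndim}")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise MaskError(f"mask values must lie in [0, 1], got range [{lo}, {hi}]")
        self.indicator = self.data >= 0.5
        if self.n < 1:
            raise MaskError("mask selects no voxels (no value >= 0.5)")

    @property
    def n(self) -> int:
        """Number of refined-region voxels."""
        return int(self.indicator.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _read_ccp4(path: str | Path) -> gemmi.Ccp4Map:
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise MapFormatError(f"cannot read MRC map {path!s}: {exc}") from exc
    mode = m.header_i32(4)
    if mode not in _ACCEPTED_MODES:
        raise MapFormatError(f"{path!s}: unsupported MRC mode {mode}")
    # Normalize the file's axis mapping to the canonical order.
    m.setup(float("nan"), gemmi.MapSetup.ReorderOnly)
    return m


def _unpack(m: gemmi.Ccp4Map, path: str | Path):
    data = np.array(m.grid, copy=True)
    if data.ndim != 3 or data.size == 0:
        raise MapFormatError(f"{path!s}: not a non-empty 3D map")
    if not np.all(np.isfinite(data)):
        raise MapFormatError(f"{path!s}: map contains non-finite values")
    voxel_size = tuple(float(s) for s in m.grid.spacing)
    origin = tuple(float(m.header_float(i)) for i in (50, 51, 52))
    return data.astype(np.float32), voxel_size, origin


def read_volume(path: str | Path) -> Volume:
    """Read an MRC density map.

    Voxel size comes from the header cell dimensions divided by the grid
    size; the MRC2014 ORIGIN record populates ``origin``.
    """
    m = _read_ccp4(path)
    data, voxel_size, origin = _unpack(m, path)
    return Volume(data, voxel_size, origin)


def read_mask(path: str | Path) -> MaskedRegion:
    """Read a refinement mask (values in [0, 1]) from an MRC file."""
    m = _read_ccp4(path)
    data, voxel_size, origin = _unpack(m, path)
    return MaskedRegion(data, voxel_size, origin)


def write_volume(vol: Volume | MaskedRegion, path: str | Path) -> None:
    """Write a volume as an MRC mode 2 (32-bit float) map."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(vol.data, dtype=np.float32))
    nz, ny, nx = vol.data.shape  # numpy axis 0 is the slow axis
    vs = vol.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(
        nz * vs[0], ny * vs[1], nx * vs[2], 90.0, 90.0, 90.0
    )
    m.update_ccp4_header(2, True)
    for i, o in zip((50, 51, 52), vol.origin):
        m.set_header_float(i, float(o))
    try:
        m.write_ccp4_map(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"cannot write MRC map {path!s}: {exc}") from exc


def validate_triplet(
    half1: Volume, half2: Volume, mask: MaskedRegion
) -> tuple[Volume, Volume, MaskedRegion]:
    """Check that two half-maps and a mask form a consistent input triplet.

    The three grids must share shape and voxel size, and the mask must lie
    in [0, 1] (enforced on construction).  Returns the inputs unchanged so
    the call can be used inline.
    """
    if half1.shape != half2.shape:
        raise ValidationError(
            f"half-map shapes differ: half1 {half1.shape} vs half2 {half2.shape}"
        )
    if mask.shape != half1.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match half-maps {half1.shape}"
        )
    for name, other in (("half2", half2.voxel_size),):
        if not np.allclose(half1.voxel_size, other, rtol=1e-4):
            raise ValidationError(
                f"voxel size mismatch: half1 {half1.voxel_size} vs {name} {other}"
            )
    if not np.allclose(half1.voxel_size, mask.voxel_size, rtol=1e-4):
        raise ValidationError(
            f"voxel size mismatch: half1 {half1.voxel_size} vs mask {mask.voxel_size}"
        )
    return half1, half2, mask
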