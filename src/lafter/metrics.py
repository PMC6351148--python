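"""Noise-suppression evaluation statistics.

Three curves judge a local filter:

* the half-set FSC between the two unfiltered half-maps;
* C_ref, the Rosenthal–Henderson figure of merit derived from it, which
  estimates the correlation of the *summed* map with a hypothetical
  noiseless map;
* the Filter-Sum xFSC, the FSC between the filtered map and the
  unfiltered sum.  A purely global (shell-wise multiplicative) filter
  scores exactly 1 in every shell; as local noise suppression becomes
  complete the curve drops towards C_ref.

The RMSD between C_ref and the Filter-Sum xFSC, up to the resolution
cutoff, summarises how close a filter comes to that ideal.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import LafterError, ValidationError
from .spectral import ShellCurve, compute_fsc
from .volume_io import MaskedRegion, Volume

__all__ = [
    "cref_from_fsc",
    "filter_sum_xfsc",
    "curve_rmsd",
    "true_xfsc",
]

logger = logging.getLogger(__name__)


def cref_from_fsc(fsc: ShellCurve, form: str = "amplitude") -> ShellCurve:
    """Figure of merit of the summed map, from the half-set FSC.

    With ``form="amplitude"`` (the default, Rosenthal & Henderson's
    convention) C_ref = sqrt(2 FSC / (1 + FSC)), which maps the half-set
    FSC of 0.143 to the figure of merit 0.5 and equals the expected
    correlation of the summed half-maps with a noiseless reference.
    ``form="power"`` gives the plain ratio 2 FSC / (1 + FSC) (its square),
    which maps FSC = 1/3 to 0.5.  Both fix 0 and 1 and are monotone.

    Shells with negative FSC are clamped to C_ref = 0: a negative figure
    of merit carries no information for the comparison.
    """
    if form not in ("amplitude", "power"):
        raise LafterError(f"unknown C_ref form {form!r}")
    f = np.asarray(fsc.values, dtype=float)
    if np.any(f <= -1.0):
        raise LafterError("FSC = -1 is a pole of the C_ref transform")
    neg = f < 0.0
    if neg.any():
        logger.warning("C_ref: %d shells with negative FSC clamped to 0",
                       int(neg.sum()))
    f = np.where(neg, 0.0, f)
    ratio = 2.0 * f / (1.0 + f)
    values = np.sqrt(ratio) if form == "amplitude" else ratio
    return ShellCurve(fsc.freqs.copy(), values, "Cref")


def filter_sum_xfsc(
    filtered: Volume,
    half1: Volume,
    half2: Volume,
    mask: MaskedRegion | None = None,
) -> ShellCurve:
    """FSC between a filtered map and the unfiltered summed half-maps.

    ``filtered`` must be at native sampling (not up-sampled).  When a mask
    is given, both maps are mask-multiplied first, matching how the
    half-set FSC is computed on experimental densities.
    """
    if filtered.shape != half1.shape or half1.shape != half2.shape:
        raise ValidationError(
            f"shape mismatch: filtered {filtered.shape}, "
            f"halves {half1.shape}/{half2.shape}"
        )
    summed = half1.data.astype(np.float64) + half2.data
    filt = filtered.data.astype(np.float64)
    if mask is not None:
        summed = summed * mask.data
        filt = filt * mask.data
    return compute_fsc(filt, summed, label="xFSC")


def curve_rmsd(a: ShellCurve, b: ShellCurve, cutoff: float) -> float:
    """Root mean squared difference between two curves up to a frequency.

    The curves must share a frequency grid; shells with frequency above
    ``cutoff`` are ignored.
    """
    if len(a) != len(b) or not np.allclose(a.freqs, b.freqs):
        raise LafterError("curves must share a frequency grid")
    sel = a.freqs <= cutoff + 1e-12
    if not sel.any():
        raise LafterError(f"no shells at or below cutoff {cutoff}")
    d = a.values[sel] - b.values[sel]
    return float(np.sqrt(np.mean(d * d)))


def true_xfsc(candidate: Volume, truth: Volume) -> ShellCurve:
    """FSC of a map against the known noiseless volume (synthetic data only)."""
    return compute_fsc(candidate, truth, label="xFSC")
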