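"""The two-stage local agreement filter.

Filter 1 walks through contiguous resolution bands with an adaptive step,
estimates the noise in each band from the half-map difference inside the
refined region, weights every voxel by the probability that it carries
signal, and re-sums the weighted bands.  Filter 2 rebuilds the map from a
cascade of low-passes of the suppressed halves, freezing each voxel at the
highest resolution at which its summed value exceeds the maximum noise.
Remaining hard edges are softened and the result is low-pass filtered at
the termination frequency.

The pipeline is deterministic: identical inputs give identical outputs.

Statistics (T, N, sigma_N, noisemax, mean signal probability) are always
accumulated over the refined region only — the mask marks where the noise
model is valid — while the per-voxel probability weighting is applied to
the whole grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.fft
from scipy.special import erf

from . import metrics
from .errors import MaskError, NoResolvableSignalError, ValidationError
from .spectral import (
    NYQUIST,
    BandSpec,
    ShellCurve,
    _butterworth_lowpass,
    apply_fourier_weights,
    compute_fsc,
    fourier_upsample,
    frequency_grid,
    lowpass_weights,
)
from .volume_io import MaskedRegion, Volume, validate_triplet

__all__ = [
    "ShellStats",
    "FilterTrace",
    "StepConfig",
    "LafterConfig",
    "RunDiagnostics",
    "shell_stats",
    "voxel_signal_probability",
    "weight_band",
    "next_band",
    "run_filter_one",
    "noise_maximum",
    "run_filter_two",
    "soften_edges",
    "lafter",
]

logger = logging.getLogger(__name__)


@dataclass
class ShellStats:
    """Noise statistics of one band-passed resolution shell.

    ``T`` is the total power sum((v1+v2)^2) and ``N`` the noise power
    sum((v1-v2)^2), both over the refined region of ``n`` voxels;
    ``sigma_N = sqrt(N/n)`` is the noise standard deviation, ``P_N = N/T``
    and ``P_S = 1 - P_N`` the noise/signal shares of the power.
    ``degenerate`` marks a band with no power (treated as pure noise).
    """

    band: BandSpec
    T: float
    N: float
    n: int
    sigma_N: float
    P_N: float
    P_S: float
    mean_p_signal: float = 0.0
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "l": self.band.l,
            "h": self.band.h,
            "T": self.T,
            "N": self.N,
            "sigma_N": self.sigma_N,
            "P_N": self.P_N,
            "P_S": self.P_S,
            "mean_p_signal": self.mean_p_signal,
            "degenerate": self.degenerate,
        }


@dataclass
class FilterTrace:
    """Record of the adaptive band walk of Filter 1."""

    bands: list[ShellStats] = field(default_factory=list)
    termination_frequency: float = 0.0
    termination_reason: str = ""

    def __post_init__(self) -> None:
        for prev, cur in zip(self.bands, self.bands[1:]):
            if not np.isclose(prev.band.h, cur.band.l):
                raise ValueError("bands must be contiguous")

    @property
    def cutoffs(self) -> list[float]:
        """Band upper edges in ascending order (the Filter-2 cascade)."""
        return [s.band.h for s in self.bands]


@dataclass(frozen=True)
class StepConfig:
    """Adaptive band-step constants (frequencies in cycles/voxel).

    The step is Delta = clamp(c * h * mean_p_signal, dmin, dmax):
    proportional to the current frequency and the mean signal probability
    of the previous band, so stepping is finest at low resolution and
    where the signal has faded.
    """

    c: float = 0.5
    dmin: float = 1.0 / 64
    dmax: float = 10.0 / 64

    @classmethod
    def for_grid(
        cls, shape: tuple[int, int, int], c: float = 0.5,
        dmin_voxels: float = 1.0, dmax_voxels: float = 10.0,
    ) -> "StepConfig":
        """Defaults of 1 and 10 Fourier voxels for an L = min(shape) grid."""
        L = min(shape)
        return cls(c=c, dmin=dmin_voxels / L, dmax=dmax_voxels / L)


@dataclass
class LafterConfig:
    """End-to-end pipeline settings."""

    fsc_threshold: float = 0.143
    step: StepConfig | None = None  # None -> StepConfig.for_grid(shape)
    upsample: int = 2               # factor for the output map; 1 disables
    force_full_range: bool = False  # ignore the FSC threshold, run to Nyquist

    def __post_init__(self) -> None:
        if not (0.0 < self.fsc_threshold < 1.0):
            raise ValueError("fsc_threshold must lie in (0, 1)")


def shell_stats(
    band1: Volume | np.ndarray,
    band2: Volume | np.ndarray,
    mask: MaskedRegion,
    band: BandSpec,
) -> ShellStats:
    """Noise statistics of one band from its band-passed half-volumes."""
    b1 = band1.data if isinstance(band1, Volume) else np.asarray(band1)
    b2 = band2.data if isinstance(band2, Volume) else np.asarray(band2)
    sel = mask.indicator
    n = mask.n
    if n == 0:
        raise MaskError("mask selects no voxels")
    s = b1[sel].astype(np.float64) + b2[sel]
    d = b1[sel].astype(np.float64) - b2[sel]
    T = float(np.dot(s, s))
    N = float(np.dot(d, d))
    if T <= 0.0:
        logger.warning("band (%.4f, %.4f): no power, treated as pure noise",
                       band.l, band.h)
        return ShellStats(band, 0.0, N, n, float(np.sqrt(N / n)),
                          1.0, 0.0, 0.0, degenerate=True)
    P_N = N / T
    if P_N > 1.0:
        # Chance fluctuation in a near-empty band; clamp to the pure-noise case.
        logger.warning("band (%.4f, %.4f): N > T (P_N = %.3f), clamped to 1",
                       band.l, band.h, P_N)
        P_N = 1.0
    return ShellStats(band, T, N, n, float(np.sqrt(N / n)), P_N, 1.0 - P_N)


def voxel_signal_probability(
    sum_value: np.ndarray | float, stats: ShellStats
) -> np.ndarray | float:
    """Probability that a voxel's band value carries signal.

    P(noise) = 1 - erf(|v1+v2| / (2 sigma_N)) is the chance of drawing a
    value at least this large from the band's noise distribution;
    the band's power shares act as a prior:

        P(signal) = P_S (1-P(noise)) / (P_N P(noise) + P_S (1-P(noise)))

    Monotone non-decreasing in |v1+v2| and in P_S.
    """
    s = np.abs(np.asarray(sum_value, dtype=np.float64))
    if stats.degenerate:
        return np.zeros_like(s) if s.ndim else 0.0
    if stats.sigma_N == 0.0:
        # Noiseless band: any non-zero density is signal.
        p = (s > 0).astype(np.float64)
        return p if s.ndim else float(p)
    p_noise = 1.0 - erf(s / (2.0 * stats.sigma_N))
    num = stats.P_S * (1.0 - p_noise)
    den = stats.P_N * p_noise + num
    out = np.zeros_like(s)
    np.divide(num, den, out=out, where=den > 0)
    return out if s.ndim else float(out)


def weight_band(
    band1: Volume | np.ndarray,
    band2: Volume | np.ndarray,
    stats: ShellStats,
    mask: MaskedRegion,
) -> tuple[np.ndarray, np.ndarray]:
    """Weight a band-passed half-volume pair by per-voxel signal probability.

    v_out = v_in * P(signal) * (h - l) / sqrt(T/n): the probability acts as
    an adaptive mask; the band width and the RMS total power normalise the
    bands against each other for the Filter-2 comparison.  Also fills in
    ``stats.mean_p_signal`` (mean over the refined region).
    """
    b1 = band1.data if isinstance(band1, Volume) else np.asarray(band1)
    b2 = band2.data if isinstance(band2, Volume) else np.asarray(band2)
    if stats.degenerate:
        stats.mean_p_signal = 0.0
        return np.zeros_like(b1, dtype=np.float64), np.zeros_like(b2, dtype=np.float64)
    p = voxel_signal_probability(b1 + b2, stats)
    stats.mean_p_signal = float(p[mask.indicator].mean())
    factor = p * (stats.band.width / np.sqrt(stats.T / stats.n))
    return b1 * factor, b2 * factor


def next_band(
    current: BandSpec, mean_p_signal: float, step: StepConfig
) -> BandSpec:
    """Next contiguous band under the adaptive stepping rule."""
    delta = float(np.clip(step.c * current.h * mean_p_signal, step.dmin, step.dmax))
    return BandSpec(current.h, min(current.h + delta, NYQUIST))


def _termination(
    fsc: ShellCurve, fsc_threshold: float, force_full_range: bool
) -> tuple[float, str]:
    if force_full_range:
        return NYQUIST, "user_limit"
    below = np.nonzero(fsc.values < fsc_threshold)[0]
    if below.size == 0:
        return NYQUIST, "nyquist"
    if below[0] == 0:
        raise NoResolvableSignalError(
            f"half-set FSC {fsc.values[0]:.3f} is below the threshold "
            f"{fsc_threshold} already in the first shell"
        )
    return float(fsc.freqs[below[0]]), "fsc_threshold"


def run_filter_one(
    half1: Volume,
    half2: Volume,
    mask: MaskedRegion,
    fsc_threshold: float = 0.143,
    step: StepConfig | None = None,
    force_full_range: bool = False,
) -> tuple[Volume, Volume, FilterTrace]:
    """Filter 1: adaptive band slicing with signal-probability weighting.

    Returns the pair of noise-suppressed half-volumes (the real-space sum
    of all weighted bands) and the trace of per-band statistics.  Bands
    start at DC and stop at the first shell whose masked half-set FSC
    falls below ``fsc_threshold`` (or at Nyquist).
    """
    validate_triplet(half1, half2, mask)
    vs = half1.voxel_size
    if not np.allclose(min(vs), max(vs), rtol=1e-4):
        raise ValidationError(
            f"the filter requires isotropic voxel sizes, got {vs}"
        )
    shape = half1.data.shape
    if step is None:
        step = StepConfig.for_grid(shape)
    fsc = compute_fsc(half1.data * mask.data, half2.data * mask.data)
    f_term, reason = _termination(fsc, fsc_threshold, force_full_range)

    F1 = scipy.fft.rfftn(half1.data.astype(np.float64))
    F2 = scipy.fft.rfftn(half2.data.astype(np.float64))
    r = frequency_grid(shape)

    out1 = np.zeros(shape)
    out2 = np.zeros(shape)
    trace = FilterTrace(termination_frequency=f_term, termination_reason=reason)

    band = BandSpec(0.0, min(step.dmin, f_term))
    lp_low: np.ndarray | None = None  # low-pass at band.l (None at DC)
    while True:
        lp_high = _butterworth_lowpass(r, band.h)
        w = lp_high if lp_low is None else lp_high - lp_low
        b1 = scipy.fft.irfftn(F1 * w, s=shape)
        b2 = scipy.fft.irfftn(F2 * w, s=shape)
        stats = shell_stats(b1, b2, mask, band)
        w1, w2 = weight_band(b1, b2, stats, mask)
        out1 += w1
        out2 += w2
        trace.bands.append(stats)
        if band.h >= f_term - 1e-12:
            break
        nxt = next_band(band, stats.mean_p_signal, step)
        band = BandSpec(nxt.l, min(nxt.h, f_term))
        lp_low = lp_high
    trace.termination_frequency = trace.bands[-1].band.h
    logger.info(
        "filter 1: %d bands, terminated at %.4f cycles/voxel (%s)",
        len(trace.bands), trace.termination_frequency, reason,
    )
    return half1.with_data(out1), half2.with_data(out2), trace


def noise_maximum(
    half1: Volume | np.ndarray, half2: Volume | np.ndarray, mask: MaskedRegion
) -> float:
    """Largest absolute half-map difference within the refined region."""
    b1 = half1.data if isinstance(half1, Volume) else np.asarray(half1)
    b2 = half2.data if isinstance(half2, Volume) else np.asarray(half2)
    sel = mask.indicator
    return float(np.abs(b1[sel].astype(np.float64) - b2[sel]).max())


def run_filter_two(
    suppressed1: Volume,
    suppressed2: Volume,
    mask: MaskedRegion,
    trace: FilterTrace,
) -> Volume:
    """Filter 2: freeze each voxel at the highest resolution beating the noise.

    Walking the Filter-1 cutoffs from the termination frequency downwards,
    both suppressed halves are low-pass filtered, summed, and compared
    against the noise maximum at that cutoff; a still-unassigned voxel
    whose |summed value| exceeds it is frozen at this cutoff's value.
    Assignment is write-once; voxels never assigned remain zero (to be
    softened afterwards).
    """
    shape = suppressed1.data.shape
    S1 = scipy.fft.rfftn(suppressed1.data.astype(np.float64))
    S2 = scipy.fft.rfftn(suppressed2.data.astype(np.float64))
    r = frequency_grid(shape)
    out = np.zeros(shape)
    assigned = np.zeros(shape, dtype=bool)
    for h in sorted(trace.cutoffs, reverse=True):
        w = _butterworth_lowpass(r, h)
        l1 = scipy.fft.irfftn(S1 * w, s=shape)
        l2 = scipy.fft.irfftn(S2 * w, s=shape)
        summed = l1 + l2
        noisemax = noise_maximum(l1, l2, mask)
        sel = ~assigned & (np.abs(summed) > noisemax)
        out[sel] = summed[sel]
        assigned |= sel
    return suppressed1.with_data(out)


def soften_edges(vol: Volume, passes: int = 8) -> Volume:
    """Spread density into unassigned (zero) voxels to remove hard edges.

    In each of ``passes`` synchronous passes, every voxel that is zero at
    the start of the pass takes the mean of its six face-neighbours'
    pass-start values (in-bounds neighbours only at the grid faces);
    non-zero voxels are untouched.
    """
    a = vol.data.astype(np.float64)
    counts = np.zeros(a.shape)
    for axis in range(3):
        sl = [slice(None)] * 3
        sl[axis] = slice(0, -1)
        counts[tuple(sl)] += 1
        sl[axis] = slice(1, None)
        counts[tuple(sl)] += 1
    for _ in range(passes):
        zero = a == 0.0
        if not zero.any():
            break
        nb = np.zeros(a.shape)
        for axis in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(0, -1)
            hi[axis] = slice(1, None)
            nb[tuple(lo)] += a[tuple(hi)]
            nb[tuple(hi)] += a[tuple(lo)]
        a = np.where(zero, nb / counts, a)
    return vol.with_data(a)


@dataclass
class RunDiagnostics:
    """Everything the pipeline measures about one run."""

    fsc: ShellCurve
    cref: ShellCurve
    filter_sum_xfsc: ShellCurve
    rmsd_cref_xfsc: float
    trace: FilterTrace
    filtered_native: Volume

    def report(self) -> dict:
        """JSON-serialisable run report."""
        return {
            "schema_version": 1,
            "termination_frequency": self.trace.termination_frequency,
            "cutoff_frequency": self.trace.termination_frequency,
            "termination_reason": self.trace.termination_reason,
            "rmsd_cref_xfsc": self.rmsd_cref_xfsc,
            "n_bands": len(self.trace.bands),
            "bands": [s.as_dict() for s in self.trace.bands],
        }

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        self.fsc.to_tsv(directory / "fsc.tsv")
        self.cref.to_tsv(directory / "cref.tsv")
        self.filter_sum_xfsc.to_tsv(directory / "filter_sum_xfsc.tsv")
        with open(directory / "report.json", "w") as fh:
            json.dump(self.report(), fh, indent=2)


def lafter(
    half1: Volume,
    half2: Volume,
    mask: MaskedRegion,
    config: LafterConfig | None = None,
) -> tuple[Volume, RunDiagnostics]:
    """Run the full two-stage pipeline on a validated half-map triplet.

    Returns the final map (optionally Fourier-upsampled for smooth
    display) and diagnostics: the masked half-set FSC, C_ref derived from
    it, the Filter-Sum xFSC of the output at native sampling, their RMSD
    up to the termination frequency, and the Filter-1 trace.
    """
    if config is None:
        config = LafterConfig()
    sup1, sup2, trace = run_filter_one(
        half1, half2, mask,
        fsc_threshold=config.fsc_threshold,
        step=config.step,
        force_full_range=config.force_full_range,
    )
    assembled = run_filter_two(sup1, sup2, mask, trace)
    softened = soften_edges(assembled)
    final = apply_fourier_weights(
        softened, lowpass_weights(softened.data.shape, trace.termination_frequency)
    )

    fsc = compute_fsc(half1.data * mask.data, half2.data * mask.data)
    cref = metrics.cref_from_fsc(fsc)
    xfsc = metrics.filter_sum_xfsc(final, half1, half2, mask=mask)
    rmsd = metrics.curve_rmsd(cref, xfsc, cutoff=trace.termination_frequency)
    diagnostics = RunDiagnostics(fsc, cref, xfsc, rmsd, trace, final)

    out = fourier_upsample(final, config.upsample) if config.upsample > 1 else final
    return out, diagnostics
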