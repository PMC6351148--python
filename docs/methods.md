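# Methods

## Model and assumptions

The filter rests on three assumptions. First, agreement between the two
half-maps is signal and disagreement is noise; this is the same assumption
underlying the half-set FSC, and it fails under over-refinement (correlated
noise leaked into both half-sets during refinement), which no post-hoc
filter can repair — the package validates inputs but deliberately does not
try to detect over-refinement. Second, within the refined region the
half-map difference is Gaussian at each resolution, so its standard
deviation σ_N = √(N/n) characterises the band's noise and the error
function gives the tail probability of a voxel value under it. Third,
macromolecular structure varies smoothly across neighbouring resolution
bands, which is what licenses operating on isolated band-passed volumes
and re-summing them.

The per-voxel weight is a prior-adjusted probability: the band's power
shares P_S and P_N act as the prior, and 1 − P(noise) stands in for the
likelihood of signal. It is not a full Bayesian posterior — that would
need a model of the signal distribution — but it suppresses noise
strongly at a negligible fraction of the cost.

## Conventions and numerical choices

* **Frequencies** are in cycles/voxel throughout; Nyquist is 0.5 and a
  "resolution of d voxels" is frequency 1/d. FSC shells are one Fourier
  voxel wide (1/L, L = min grid dimension), valued at the shell centre;
  shells with zero power in either input report 0 with a warning.
* **Transforms** are real-to-complex (scipy.fft); shell sums carry
  Hermitian multiplicity weights so statistics match the full transform.
* **Absolute values.** The erf argument uses |v1+v2| and the noise
  maximum uses max|v1−v2|. Without them the noise probability exceeds 1
  for negative sums and the noise maximum can be negative; the absolute
  value is the only self-consistent reading, and it also lets strong
  negative density survive Filter 2 (density sign is a contrast
  convention). Signal probability is therefore even in the voxel value.
* **C_ref** defaults to the amplitude form √(2·FSC/(1+FSC)), which fixes
  the 0.143 ↔ 0.5 anchor and equals the expected correlation of the
  summed map with a noiseless reference (derivable from FSC = S/(S+N)).
  The plain power ratio 2·FSC/(1+FSC), occasionally quoted in the
  literature, is available as `form="power"`; it maps FSC = 1/3 to 0.5
  and does *not* reproduce the measured sum-vs-truth correlation.
  Negative-FSC shells clamp C_ref to 0 (logged): a negative figure of
  merit carries no information for the comparison.
* **Adaptive step**: Δ = clamp(c·h·P̄_signal, Δ_min, Δ_max) with c = 0.5,
  Δ_min = 1 and Δ_max = 10 Fourier voxels. Only the proportionality is
  dictated by the method; the constants are exposed in the configuration
  and logged on every run. The first band starts at DC (l = 0) and is one
  Fourier voxel wide; bands are capped at the termination frequency so
  the walk ends exactly there.
* **Termination** uses the mask-multiplied half-set FSC (all evaluation
  curves are computed on masked densities); the default threshold is
  0.143. A first shell already below threshold raises a dedicated
  "no resolvable signal" error. Near-empty bands where chance makes
  N > T clamp P_N to 1 (pure noise) with a warning.
* **Filter 2** reuses exactly the band boundaries of Filter 1 as its
  low-pass cascade, descending from the termination frequency; voxel
  assignment is write-once.
* **Softening** runs exactly 8 synchronous passes: voxels zero at the
  start of a pass take the mean of their six face-neighbours' pass-start
  values (in-bounds neighbours at grid faces); non-zero voxels never
  change. Because filled voxels are frozen, a one-voxel gap bridges in a
  single pass at a value below the flanking density — the rule spreads
  density into unassigned regions, it does not produce a monotone
  interpolant.
* **Output normalisation.** Filter 1 scales each band by (h−l)/√(T/n) to
  make bands comparable for the noise-maximum test; the scaling is never
  undone, so output amplitudes are band-normalised (approximately
  whitened across the pass band). Shell-correlation metrics are blind to
  per-shell scaling, and for display the effect resembles conventional
  map sharpening. The written map is 2× Fourier-upsampled by default;
  all metrics are computed at native sampling.
* The pipeline is seed-free and deterministic: reruns are bit-identical.
* Anisotropic voxel sizes round-trip through I/O but are rejected by the
  filter, whose radial machinery assumes isotropic sampling.

## Synthetic data generator

The generator emulates controlled half-map experiments. A non-negative
procedural phantom (Gaussian beads along a smooth closed random curve
plus broad lobes, or a helical tube; geometry seeded from the phantom
name only, so the truth is identical across noise seeds) is band-limited
with the same Butterworth response used by the filter — either a flat
cutoff or a gradient along one axis, the latter approximated by per-slice
log-linear interpolation between 12 globally low-passed copies, since
spatially varying filtering is not separable in Fourier space.

Half-maps are `truth + noise` with independent Hermitian-symmetric
complex Gaussian noise, realised by colouring real-space white noise so
reality is exact. Per shell the noise power is S·(1/FSC − 1), with S the
shell power of the *untruncated* phantom: below the cutoff the expected
half-set FSC is flat at the target, and beyond it the same noise-to-signal
calibration continues where the signal has been removed — noise but no
signal past the cutoff, the regime a real reconstruction terminates in.
Per-shell (rather than global) noise scaling is the only choice that
yields a flat FSC. The mask is a separable soft-edged box (2-voxel
margin, 5-voxel cosine taper) enclosing the phantom support; a sphere
large enough to enclose it would hit the grid faces at these box sizes,
and the hard truncation leaks spectrally and visibly deflates every
masked FSC.

What the generator does not emulate: electron optics (CTF, dose,
projection geometry), solvent flattening, refinement artefacts, masking
or symmetry-induced half-set correlation. Passing tests therefore
demonstrate correct behaviour under the stated noise model, not
robustness to over-refinement on real data.

## Validation experiments and problem sizes

All reference experiments run at 64³ with truncation at 4 voxels (cutoff
0.25 cycles/voxel), a size at which the full pipeline runs in seconds and
the shell statistics are still meaningful.

* **C_ref consistency**: with flat FSC 0.5, C_ref from the measured
  half-set FSC is compared against the directly measured xFSC of the
  summed map versus the truth, as an RMSD up to the cutoff with both
  curves averaged over 5 seeds (averaging first estimates the asymptotic
  agreement rather than per-realisation shell noise). At 64³ the
  innermost shell holds only ~13 independent Fourier coefficients, which
  sets a sampling floor of roughly 0.015 on this RMSD at 5 seeds; with 30
  seeds the measured value falls to ~0.003, confirming the estimator is
  unbiased and the agreement is exact up to finite-size noise.
* **Global-filter identity**: a strictly shell-wise multiplicative filter
  applied to the summed map leaves the Filter-Sum xFSC at 1 to machine
  precision in every signal-bearing shell. (A *continuous* radial
  transfer function such as a Butterworth deviates at the 10⁻³ level
  because it varies slightly within a binned shell.)
* **Low-SNR recovery**: at flat FSCs 0.333, 0.144 and 0.072 (3 seeds
  each, termination forced to Nyquist) the filtered map's shell-mean xFSC
  against the truth is compared with the summed map's. The filter wins at
  all three levels on these phantoms, with margins of roughly +0.24,
  +0.37 and +0.42 — the advantage grows as noise grows, because zeroing
  voxels indistinguishable from noise removes most noise power while the
  strong multi-scale features remain detectable. On solid
  constant-density phantoms the 0.072 margin narrows to about +0.1.

## Known limitations

* Extreme-value statistics make the noise maximum conservative on large
  grids: the more voxels in the mask, the higher the bar for assignment.
* Specks of high-frequency noise can survive in regions of very low
  local resolution; they appear only at very low contour levels.
* Band normalisation means output amplitudes are not on the input scale.
* The filter trusts its mask: a wrong refined-region mask invalidates the
  noise statistics, and over-refined inputs will have their correlated
  noise preserved as "signal".
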