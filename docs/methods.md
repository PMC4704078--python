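# Methods

## Problem setting and model

A crystal rotates continuously about a single axis perpendicular to the
X-ray beam while a photon-counting detector records millions of extremely
short exposures. Each sparse frame holds ~200 photons, of which ~80% come
from smooth diffuse scatter (solvent, air, windows); Bragg peaks are
invisible in any single frame. The only prior knowledge is an approximate
tetragonal unit cell, the rotation-axis direction and the detector
geometry; the rotation angle of each frame is treated as unknown.

The estimator is expectation-maximization on the Poisson likelihood of the
photon counts (the EMC algorithm restricted to 1-D rotations). The latent
variable is each frame's rotation among `J` uniform samples; the parameter
is the 3-D intensity `W(q)` on a cubic reciprocal voxel grid, which
includes both Bragg peaks and the diffuse background. One iteration:
**expand** `W(q)` into per-rotation Ewald-sphere slices by trilinear
interpolation; compute orientation probabilities `P_jk` in the log domain
(log-sum-exp per frame, uniform prior; only nonzero counts enter the
product term, the exponential term is the slice total); **maximize**
(`W'_ij = Σ_k P_jk K_ik / Σ_k P_jk`); **compress** the slices back with
adjoint trilinear weights and per-voxel weight normalization. Convergence
is monitored by the relative RMS change of the 3-D intensity and by the EM
objective `Σ_k log Σ_j (1/J) Π_i Poisson(K_ik; W_ij)`, which must be
non-decreasing up to interpolation tolerance (asserted at 0.1% of its
magnitude in the tests).

Assumptions: fixed exposure per frame and a single crystal, so slices are
expected counts per frame and no per-frame scale factors are fitted; no
solid-angle or polarization corrections (an optional per-pixel weight hook
is the place to add them); elastic scattering only.

### Seeding and gauge

The initial intensity places 3-D Gaussian bumps of random height at every
Bragg position predicted from the approximate cell **and** the known
lattice orientation, plus a uniform floor of 1e-10 expected counts (a
photon observed where the model is zero must not produce −∞). No symmetry
is imposed: forbidden reflections and both Friedel mates are seeded
independently, so symmetry present in the converged map is a genuine
diagnostic of orientation recovery. Because a reconstruction from
non-oriented single-axis frames is defined only up to a global rotation
about the axis, every truth comparison first fits a gauge offset on the
rotation grid (with an optional sense flip); seeding at predicted
positions pins the gauge near zero in practice, which is also what makes
integration with the known orientation matrix meaningful.

The seed's overall scale is normalized to the mean observed photon count
before the first iteration; the M-step makes the scale self-consistent
afterwards. Rotation rows that receive negligible probability weight in an
M-step inherit the previous iteration's slices instead of being zeroed.

## Synthetic data generator

The generator is first-class, tested code: it defines the study conditions
under which every claim is measured.

* **Cell and peaks.** Tetragonal toy cell a = b = 32, c = 36 Å in a random,
  recorded orientation (lattice axes deliberately not grid-aligned).
  Intensities are Wilson-like — exponential random heights attenuated by
  `exp(−B|q|²/2)` with B = 25 Ų — so bright low-resolution and dim
  high-resolution peaks coexist. Friedel symmetry is imposed by averaging
  mate pairs; the axial reflection conditions 00l: l = 4n and h00: h = 2n
  (the tetragonal screw/2₁ absences) zero the forbidden classes unless
  switched off. Peaks are isotropic Gaussians of width 0.13 a*
  (≈ 0.9 voxel at the default a*/7 sampling).
* **Background.** A smooth isotropic radial profile (wide Gaussian plus
  pedestal) on the same grid. Its magnitude is set by the target
  background fraction, 0.8 by default.
* **Calibration.** Peak and background maps are scaled so that, averaged
  over the rotation samples, a frame's expected total is the target mean
  (200 photons) with the stated background share. Frames are independent
  Poisson draws from trilinear slices of the calibrated model — the same
  interpolation the EMC expansion uses, so simulator and estimator share
  one forward model and the calibrated model is an exact oracle for
  probability computations.
* **What it does not emulate.** Structure factors from atoms, absorption,
  detector point-spread/charge sharing, per-frame beam jitter, radiation
  damage, and analog-frame thresholding. Passing tests therefore
  demonstrate the statistical machinery (orientation recovery under
  Poisson noise, segmentation, integration), not detector physics.

## Peak analysis

Segmentation is the iterated local standard score: pass 1 computes μ and σ
over every voxel of the surrounding n³ window (n = 15); three further
passes recompute them from the voxels still labelled background, with the
threshold rising γ = 1.0, 1.7, 2.3, 3.0 (linear spacing between the
stated endpoints). Windows with σ = 0 classify a voxel as signal only if
it lies strictly above the (constant) local level. Unobserved voxels are
excluded from the statistics. Segmentation is deterministic, invariant
under affine rescaling of the map, and monotone in the schedule.

Integration assigns every voxel to its nearest predicted Bragg position in
fractional Miller space; an ellipsoid with principal semi-axes
proportional to (a*, a*, c*) occupying a volume fraction f of the
reciprocal cell is a sphere of radius `(3f/4π)^(1/3)` there, so membership
is a single distance test and neighbouring ellipsoids (f ≤ 50%) can never
overlap. Each reflection uses the smallest fraction from {10%, 25%, 50%}
that captures its segmented voxels (the largest when no segmentation is
supplied); the local background mean — background voxels sharing the
reflection's fractional cell — is subtracted per voxel. σ(I) is propagated
from the local background variance (`σ_I² = n_sig σ_bg² (1 + n_sig/n_bg)`),
a package convention. Reflections whose window leaves the map, touches
unobserved voxels or an exclusion zone are flagged partial and carry no
intensity. Negative intensities are retained in the CSV and clipped at
zero only when converting to amplitudes (flagged per row).

Lattice refinement grid-searches (a*, c*) over ±2% in 11 steps, scoring
the segmented-signal intensity inside small ellipsoids (1% of the cell) at
each candidate's predicted positions; ties break toward the input
estimate. **Limitation:** at desk-scale resolution the c* gradient is weak
— with 0.13 a* peaks a 1% c error shifts the outermost l layer by less
than half a peak width in fractional coordinates — so reliable recovery
requires peaks narrower than the refinement ellipsoid (demonstrated in
tests at 0.06 a*). At full experimental resolution (l up to ~18) this is
not a constraint.

## Validation metrics

* **Reference assembly** deposits photons at their hidden true rotations
  with the same trilinear adjoint, i.e. exactly one maximize+compress with
  one-hot probabilities; it is the "knew the orientations all along"
  baseline.
* **Amplitude R factor** `R = Σ| |F_ref| − s|F_rec| |/Σ|F_ref|` over
  common non-partial reflections, with s a least-absolute-residual global
  scale (weighted median of amplitude ratios; can be fixed to 1). Both
  lists come from the *same* segmentation/integration settings so R
  isolates orientation-recovery error.
* **Orientation errors**: per-frame argmax of `P_jk` versus truth after
  fitting the gauge; "correct" means within max(1°, half the rotation
  spacing), so the metric stays meaningful on coarse grids.
* **Background share**: the summed intensity over background-labelled
  voxels of the reconstruction after rescaling its total to the recorded
  photon count. The estimate is biased low by background sitting under
  signal-labelled voxels and high by unsegmented peak tails; at the
  benchmark scale the net bias is within a percentage point.

## Benchmark scenes and numerical choices

Two frozen scenes (see `RunConfig`) keep the sparse regime — 200
photons/frame, 80% background, 1.54 Å, 33 mm detector distance — and scale
the rest to desk size:

* **Orientation benchmark**: 225³ grid at a*/7 (2.0 Å reach, matching the
  experiment's orientation stage), 360 rotations at 1°, 6000 frames,
  probabilities against the calibrated truth. The rotation-to-voxel
  leverage matters: a 1° step moves a resolution-limit peak by ~2 voxels
  here; coarser grids measurably lose assignment accuracy.
* **Reconstruction benchmark**: 95³ grid at a*/7 (4.8 Å), 120 rotations at
  3°, 20 000 frames, 30 EMC iterations. 120 rotations rather than more:
  with 3° steps a rim peak moves ~2.5 voxels (~2.7 peak widths) per step,
  enough to avoid the adjacent-bin ambiguity in which EM settles into an
  azimuthally smeared fixed point.

Other numerical choices: trilinear interpolation for both expand and
compress (the minimal adjoint-consistent pair); probability floor 1e-10;
maximize weight cutoff 1e-12; compress weight floor 1e-8 (below it a voxel
is "unobserved"); deterministic frame ordering and a single master seed
per run, echoed into run logs; all randomness through
`numpy.random.default_rng`.

Known limitations: 1-D rotation group only (full 3-D orientation sampling
is out of scope); no per-frame scale/partiality refinement; single-panel
detector metrology; maps store no observed-voxel flags on disk (zero
voxels read back as unobserved).
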