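# emcryst

Reconstruction of a crystal's three-dimensional Bragg intensity from huge
numbers of **non-oriented, sparse diffraction frames** — exposures so short
(~200 photons each, ~80% of them diffuse background) that no peak can be
seen, let alone indexed, in any single frame — collected while the crystal
rotates about a single known axis.

This is the regime of serial microcrystallography at storage-ring sources:
the crystal is too small (or the exposure too short) for frame-by-frame
indexing, but millions of cheap sparse frames are easy to record. `emcryst`
implements the EMC (expand–maximize–compress) algorithm restricted to the
one-dimensional rotation group, plus everything around it: a statistical
frame simulator, 3-D Bragg peak segmentation and integration, and
validation metrics. It is aimed at method developers who want a complete,
testable desk-scale model of such an experiment.

## The model

Let `W(q)` be the mean scattered intensity on a reciprocal-space voxel
grid, and let `W_ij` be its tomographic slice on the Ewald sphere: the
expected photon count at detector pixel `i` when the crystal sits at
rotation `Ω_j`. Frame `k` records Poisson counts `K_ik`. With a uniform
prior over the `J` sampled rotations, the conditional probability that
frame `k` was taken at rotation `j` is

    P_jk ∝ ∏_i W_ij^K_ik · exp(−W_ij),

and the expectation-maximization update of the slices is

    W'_ij = Σ_k P_jk K_ik / Σ_k P_jk .

Each iteration expands `W(q)` into slices (trilinear interpolation),
computes `P_jk` in the log domain, applies the update, and compresses the
slices back into 3-D with adjoint trilinear weights. The reconstruction is
determined only up to a global rotation about the axis (the gauge); seeding
with Gaussian bumps at the Bragg positions predicted from an approximate
cell both accelerates convergence and pins the gauge in practice. No
symmetry (Friedel pairs, systematic absences) is ever imposed, so recovered
symmetry is evidence the orientations were found.

Downstream, voxels are classified signal/background by an iterated local
standard score `z = (W − μ)/σ` (window `n³`, threshold schedule
γ = 1.0 → 3.0), reciprocal-lattice constants are refined by grid search on
the segmented intensity, and reflections are integrated in ellipsoidal
windows (10–50% of the reciprocal cell) with local background subtraction.
Quality is quantified against the *reference* intensity assembled from the
(hidden) true orientations via the amplitude R factor
`R = Σ| |F_ref| − s|F_rec| | / Σ|F_ref|`.

## Worked example

```python
from emcryst import EMCModel, RunConfig, emc, peaks, validate
from emcryst.simulate import make_ground_truth, simulate_dataset

cfg = RunConfig.toy()                      # 63³ grid, 60 rotations, 2000 frames
cell, grid, geom, rot = cfg.cell(), cfg.grid(), cfg.detector(), cfg.rotations()
truth = make_ground_truth(cell, grid, cfg.peak_sigma_q(), rng_seed=0)
frames = simulate_dataset(truth, geom, rot, cfg.n_frames, rng_seed=1)

model = EMCModel(frames, geom, rot, grid, cell=cell,
                 orientation=truth.orientation, peak_sigma_q=cfg.peak_sigma_q())
result = model.fit(n_iter=10, rng_seed=2)
print(result.summary())
```

```
EMC reconstruction results
========================================
frames                         2000
total photons                399808
mean photons / frame         199.90
rotation samples                 60
rotation spacing (deg)       6.0000
grid extent                   63^3
voxel size (1/A)           0.004464
resolution limit (A)          7.226
iterations run                   10
final RMS change          1.824e-03
final log-likelihood   -1.280188e+06
observed voxels              186349 / 250047
```

Continuing with integration and validation:

```python
reference = validate.assemble_reference(frames, geom, grid)
seg = peaks.segment_peaks(result.intensity, cfg.window, cfg.gamma_schedule)
seg_ref = peaks.segment_peaks(reference, cfg.window, cfg.gamma_schedule)
refl = peaks.integrate_reflections(result.intensity, cell, truth.orientation,
                                   cfg.window_fractions, seg)
refl_ref = peaks.integrate_reflections(reference, cell, truth.orientation,
                                       cfg.window_fractions, seg_ref)
```

prints, on this 2000-frame toy scene:

```
amplitude R vs reference: 7.55%
background photon share:  81.1%
frames in correct 6-deg bin: 79.0% (gauge offset 0 deg)
```

The R factor compares reflections integrated identically from the EMC
reconstruction and from the true-orientation reference, so it isolates the
cost of *not knowing* the orientations; the background share is read off
the segmented, photon-rescaled map (simulator truth: 80%). At the package's
benchmark scale (20 000 frames, 120 rotations, 95³ grid;
`RunConfig.reconstruction_benchmark()`) the same pipeline reaches R ≈ 3%,
and orientation assignment against the true intensity at 2.0 Å
(`RunConfig.orientation_benchmark()`) places ≥ 99.7% of frames within 1°.

A four-command CLI (`emcryst simulate | reconstruct | integrate |
validate`) wraps the same pipeline for shell use; every command is driven
by one YAML config and a master seed, and all outputs (HDF5 frame
container, CCP4 maps, SHELX-style hkl, CSV/JSON reports) round-trip through
the readers in `emcryst.io`.

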