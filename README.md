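# astigtrack

Astigmatic 3D single-particle feedback tracking, in software: synthetic
astigmatic image stacks, two-template axial localization, a closed-loop
focus-feedback simulator, offline trajectory assembly, and the statistics
needed to find mobility states and their transitions in single trajectories.

## The problem

Single fluorescent particles — lipids in a membrane, mRNP or rRNP particles
in a cell nucleus — diffuse out of the < 1 µm axial detection range of a
high-NA microscope within a few frames, so intracellular trajectories
rarely exceed 10–20 localizations. Active feedback tracking fixes this: the
axial position of the particle is estimated from the shape of its
astigmatic image *every frame*, and a piezo stage re-centres the focal
plane before the next frame, extending observation to hundreds or thousands
of localizations at a few hundred photons per frame. Long single
trajectories, in turn, make single-molecule statistics possible that
ensembles of snippets cannot deliver: per-trajectory mobility fractions and
exact significance tests for transient immobilization.

This package implements that computation chain end to end on synthetic
data, so every stage is testable without an instrument:

1. **simulate** — elliptical-Gaussian PSF with the astigmatic width law
   σ(z) = σ₀√(1 + ((z − z_f)/d)²) per axis, EMCCD-like noise
   (Poisson × excess factor + read noise), Brownian motion with
   Markov-switched diffusion coefficients.
2. **calibrate** — two PSF templates cut from a bead stack at
   z_rel = ±400 nm; normalized covariance (ZNCC) values ξ₁, ξ₂ of an
   unknown spot with the two templates give the linear axial metric
   (ξ₂ − ξ₁)/(ξ₁ + ξ₂) = a·z_rel + b.
3. **localize** — intensity peak + background-subtracted centroid laterally;
   z_rel = ((ξ₂ − ξ₁)/(ξ₁ + ξ₂) − b)/a axially, single pass, no iteration.
   An elliptical-Gaussian least-squares fit is included as the conventional
   (slower) reference estimator.
4. **feedback** — the closed loop: localize, command a stage move
   −gain·ẑ_rel with one frame latency, declare loss outside a capture
   range; absolute coordinates are recovered as z_abs = stage_z + z_rel.
5. **track** — offline detection of all particles by template correlation,
   mutual-nearest-neighbour linking with termination on ambiguity,
   assembly against the stage trace.
6. **mobility** — MSD fits and cumulative jump-distance distribution (CJDD)
   mixture fits, P(r², Δt) = 1 − Σᵢ aᵢ·exp(−r²/(4DᵢΔt)), including global
   fits with diffusion coefficients shared across trajectories and free
   per-trajectory fractions.
7. **states** — threshold classification of jumps into slow/fast states and
   two exact tests against the i.i.d. null: the probability of a same-state
   run of length ≥ k among n Bernoulli-classified jumps (an alternating
   closed-form sum, with a stable recurrence for large n), and the
   transition-count deficit against ⟨s′⟩ = 2·p_A·p_B·n, σ = √(p_A·p_B·n).

## Worked example

Calibrate from a synthetic bead stack, feedback-track a diffusing particle
for 600 frames, and analyse the reconstructed trajectory:

```python
import numpy as np
import astigtrack as at
from astigtrack.mobility import jump_sequence, JumpDistanceMixture
from astigtrack.states import classify, scan_thresholds, transition_stats
from astigtrack.track import Trajectory

psf, cam = at.PsfModel(), at.CameraModel()
stack, z = at.render_calibration_stack(psf, cam, -1.0, 1.0, 0.05,
                                       photons=5000, noise=False)
t1, t2 = at.extract_templates(stack, z, offset=0.4, size=11)
curve = at.fit_calibration(stack, z, t1, t2)

motion = at.MotionModel(diffusion_coefficients=(1.0,), frame_interval=0.0165)
res = at.run_closed_loop(motion, psf, cam, curve, 600, photons=300.0, rng=42)

locs = [l for l in res.localizations if l is not None]
traj = Trajectory(frames=[l.frame for l in locs],
                  t_s=[l.frame * 0.0165 for l in locs],
                  x=[l.x for l in locs], y=[l.y for l in locs],
                  z_rel=[l.z_rel for l in locs])
jumps = jump_sequence(traj, dims="xy")
print(JumpDistanceMixture(jumps.r2, jumps.dt, 1).fit().summary())
print(transition_stats(classify(jumps, float(np.median(jumps.r2)))))
print(scan_thresholds(jumps))
```

prints

```
calibration: a = 0.3984 1/um, b = -0.0000, valid range -0.60..0.60 um
tracked 600/600 frames, retained=True
axial span covered: 6.20 um
Jump-distance mixture fit
  components: 1   jumps: 599   dt: 16.50 ms   kernel: 2D
  residual SS: 5.576e+02   converged: True
  comp        D (um^2/s)        fraction
     1    1.1369 ± 0.0030    1.000 ± 0.000
transitions: s = 309, expected 299.5 +/- 12.2 (z = -0.78, tail p = 0.781)
significant dwells: []
```

Reading this: at 300 photons/frame the loop held the particle for all 600
frames and covered 6.2 µm axially — about five times the static detection
range. The single-component CJDD fit returns D slightly above the
simulated 1.0 µm²/s because localization noise adds to every squared jump
(see `docs/methods.md`). The transition count matches the i.i.d.
expectation (z = −0.8) and the dwell scan finds nothing — correct, since
this particle has a single mobility state.

A `astigtrack` command-line tool wraps the same pipeline
(`simulate stack|path`, `calibrate`, `track-live`, `track`,
`analyze mobility|states`); every stochastic command takes `--seed` and
writes its resolved configuration for reproducibility.

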