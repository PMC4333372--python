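# Methods

This note records the models behind `astigtrack`, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests do
and do not demonstrate about real microscope data.

## Optical and camera model

The PSF is an elliptical Gaussian whose axis widths follow the
Gaussian-beam law

    sigma_axis(z) = sigma0 * sqrt(1 + ((z - z_focus_axis) / d)^2),

with the x focal plane at −s/2 and the y focal plane at +s/2 (s = focal
separation introduced by the cylindrical lens). The effective focal plane
(z_rel = 0) is where both widths are equal. Defaults: sigma0 = 0.16 µm,
depth scale d = 0.4 µm, focal separation s = 0.8 µm, pixel size 0.24 µm —
representative of a high-NA water-immersion detection path with ~60×
effective magnification; all configurable. This is a phenomenological
model: no vectorial diffraction, aberrations, or field dependence.

Rendering integrates the Gaussian over the pixel grid (erf differences), so
the noise-free pixel sum equals the photon count exactly. The noise model
is Poisson shot noise on signal + background scaled by an EM excess factor
F (default √2, the high-gain EMCCD limit) plus Gaussian read noise:
mean preserved, variance F²·mean + read². The defaults
(background 2.0 photons/pixel, read 0.5) give an effective background
s.d. of ≈ 2 photons/pixel, the low-background light-sheet regime the
package emulates. SNR is defined as peak pixel amplitude above the mean
background divided by the background s.d.; `photons_for_snr` inverts this
definition for a pixel-centred emitter.

Motion is Brownian: per-axis Gaussian increments of variance 2·D·Δt, with
an optional discrete-time Markov chain over mobility states (per-frame
leave probability 1 − exp(−rate·Δt), split proportionally among
destinations). The chain's stationary occupancy matches the
continuous-time rate ratio only for rate·Δt ≪ 1; at rate·Δt ≳ 0.5 the
discretisation shifts it, which is a property of the sampling, not a bug.

## Axial calibration and localization

Two templates (11×11 px by default, 9–11 supported) are cut from a
calibration stack at z_rel = ∓0.4 µm, centred on the intensity peak
(located after mild Gaussian smoothing so single noise pixels cannot
hijack the cut). "Normalized covariance" is the Pearson correlation
between template and equal-size patch (zero-mean normalized
cross-correlation): bounded in [−1, 1] and invariant under affine
intensity transforms, which is what makes the axial metric independent of
photon count. Per slice (and per localization) the covariance pair
(ξ1, ξ2) is read at the pixel maximizing ξ1 + ξ2, ties broken row-major.
The metric (ξ2 − ξ1)/(ξ1 + ξ2) is fitted with a least-squares line over
the inter-focal region; the curve's valid range is the measured monotone
span of the metric (typically ±0.6 µm with the defaults), which always
contains the fitted range.

Numerical behaviour worth knowing:

- **Metric curvature.** The metric is S-shaped; the straight-line fit
  leaves a maximum residual of ≈ 4% of the metric span with the default
  PSF, i.e. a systematic pointwise axial error up to ≈ 20 nm at
  z ≈ ±0.2 µm. The error is antisymmetric, so the estimator is unbiased in
  the mean over the range.
- **Sub-pixel alignment.** Covariances are evaluated at integer pixel
  shifts only. A laterally half-pixel-offset emitter biases ẑ by up to
  ≈ 0.1 µm with 0.24 µm pixels. Averaged over random sub-pixel positions
  this contributes an axial scatter floor of ≈ 0.05–0.07 µm that does not
  improve with photon count; it is the dominant reconstruction error at
  high SNR. Finer pixels reduce it.
- **Selection bias at low SNR.** Picking the max-(ξ1+ξ2) pixel on noisy
  data preferentially selects upward noise in the denominator and
  attenuates the metric: refitting the calibration slope from single
  noisy stacks gives ≈ −20% at SNR 5 and ≈ 0% at SNR 50. Bead
  calibrations average many exposures per z step; with ≈ 20 averaged
  exposures the slopes at SNR 5 and SNR 50 agree to < 1%, and localization
  of (non-averaged) low-SNR particles against a high-SNR calibration is
  unbiased. Calibrate from bright or averaged stacks.
- **Detection floors.** A covariance below 0.1 is treated as uninformative
  when delimiting the calibration's valid range; localization declares
  no-detection only when both covariances fall below 0.25, because the
  maximum of a noise-only correlation over the 5×5 search neighborhood
  reaches ≈ 0.15–0.2.

Lateral localization is a background-subtracted centroid (background =
mean of the window border, negative residuals clipped); on noise-free
input it is exact to < 0.01 px across sub-pixel offsets. The photon
estimate is the background-subtracted window sum — rendered images are
already photon-calibrated, so no gain conversion applies. The
elliptical-Gaussian fit (pixel-integrated model, Levenberg–Marquardt)
recovers model widths to < 2% and serves as the precision reference: at
SNR 8 the template metric's axial scatter is within 1.1× of the
width-fit estimator's.

## Feedback loop

Per frame: render the particle at its true offset from the focal plane,
localize, command a sample move of −gain·ẑ_rel (estimate clamped to the
calibration's valid range; hold on no-detection or out-of-range metric),
apply it `latency` frames later. The stage trace records the focal-plane
position in specimen coordinates, which *decreases* by the commanded
sample move; absolute coordinates are z_abs = stage_z + z_rel. Lateral
motion is followed by re-centring the rendered region of interest on the
previous localization, mimicking the on-camera search window. Loss is
declared when the true offset exceeds the capture range (default ±1 µm)
or after 3 consecutive failed localizations. Stage dynamics are idealized
(instantaneous, no settling, no hysteresis).

For a particle moving at constant axial speed v the loop's steady-state
lag is v·Δt/gain for any latency (the measured offset feeds back the
accumulated lag); latency affects stability margin, not the asymptotic
lag. With the defaults (1.12 ms frames, gain 1, latency 1, 300
photons/frame) the loop retains a D = 10 µm²/s particle for 1000 frames
in > 90% of runs; failures set in near D ≈ 15–20 µm²/s where the
per-frame axial step s.d. (≈ 0.2 µm) approaches the usable metric span.

## Trajectory assembly

Offline detection correlates each frame with both templates, takes local
maxima of the pixelwise maximum map above a threshold (default 0.4 ≈ 4.4
s.d. of the noise-only correlation — at SNR 6 this detects ≈ 98% of
spots with ≈ 0.03 false maxima per 64×64 frame), and refines candidates
with the centroid/axial estimators. Linking is mutual-nearest-neighbour
within a user-supplied displacement limit, measured in 3D by default
(configurable to lateral-only); *any* localization with two or more
candidates within the limit is an ambiguity and all trajectories involved
terminate at that frame — conservative and appropriate at the sub-pM
densities the method targets. No gap closing: a missed detection ends a
trajectory, so sustained fragmentation below 5% needs per-frame detection
above ≈ 97%. Trajectories shorter than 3 localizations are dropped.

## Jump-distance mixture fitting

For 2D Brownian motion the squared frame-to-frame displacement is
exponential, so the CDF of a mixture of m mobility states is
1 − Σ aᵢ·exp(−r²/(4DᵢΔt)) with Σaᵢ = 1. 3D Euclidean displacements on a
gently curved membrane may be analysed with the same 2D kernel
(displacement ≪ curvature radius); a genuine 3D kernel
erf(x) − 2x·e^(−x²)/√π is available via `dims=3`.

The default estimator is least squares of the model CDF against the
empirical CDF at the sorted sample points, weighted by the inverse ECDF
standard deviation √(P(1−P)/n). The weighting matters: with two close
components (D ratio ≈ 2, 3000 jumps) the unweighted fit overestimates a
30% slow fraction by ≈ 7 percentage points on average, while the weighted
fit is within ≈ 3; an exponential-mixture MLE (`fit_mle`) is provided as
an independent cross-check. Parameters are log-D plus softmax fractions,
multi-started from a fixed ladder of D values around the sample scale —
deterministic given the data. Standard errors come from the Gauss–Newton
covariance with a delta-method transform; for close components they are
optimistic (the likelihood surface is shallow) and seed-to-seed scatter
is the more honest uncertainty.

The global fit shares one D set across trajectories with free
per-trajectory fractions, initialized from the pooled fit; the pooled
fractions it reports are refitted on the concatenated data with the
shared D fixed — the natural companion to per-trajectory fractions that
may individually span 0–100%.

Localization noise inflates every squared jump by ≈ 4σ_loc² per 2D jump,
biasing fitted D upward by that amount over 4Δt (about +10% at
σ_loc ≈ 0.04 µm, Δt = 16.5 ms, D = 1 µm²/s); MSD fits absorb the same
term into their intercept instead, which is why the MSD route is
preferred for absolute single-state D estimates (weighted line through
the first 5 lags by default).

## Run-length and transition statistics

Thresholding squared jumps at r²_lim labels each jump slow (A, with
probability p_A = empirical CDF at the threshold) or fast (B). Under the
i.i.d. null the labels are Bernoulli trials, and the probability that n
trials contain **no** success run of length ≥ k has the closed form

    sum_{m=0}^{floor((n+1)/(k+1))} (−1)^m p^{mk} (1−p)^{m−1}
        [ C(n−mk, m−1) + (1−p)·C(n−mk, m) ].

The dwell significance P′ is its complement — the probability of at least
one such run — small values flagging non-random immobilization
(P′ < 0.05 by convention). Two evaluation routes are mathematically
identical and cross-checked: the alternating sum (used when its largest
term stays below ~1e12, which covers dwell-scale k) and the stable linear
recurrence f(i) = f(i−1) − (1−p)·p^k·f(i−k−1) (used for small k / large n,
where the sum's cancelling terms exceed double precision — evaluating the
sum naively there is catastrophically wrong, not merely inaccurate). Both
match exhaustive enumeration to 1e−12 for n ≤ 16.

Design choices: p for a dwell's significance is the whole-trajectory ECDF
including the candidate dwell, which biases p upward and makes the test
conservative; the maximal run in *either* state is annotated, the
threshold scan searching slow-state dwells by default. The scan tries
every midpoint between distinct sorted r² values and deduplicates
overlapping significant events (keeping the lowest P′), reporting raw
uncorrected P′ values. At a *fixed* threshold the test is exact and
conservative (measured false-positive rate ≈ 0.01 at α = 0.05); the
*union over all thresholds* is multiplicity-inflated (≈ 0.4 of pure
Brownian trajectories of ~250 jumps yield at least one raw event at
α = 0.05) — interpret scan output as candidates for inspection, or use
the `bonferroni=True` mode for family-wise control. Detection power for a
genuine 30-frame immobilization in a 300-jump trajectory is ≈ 100%.

The transition test counts label changes s between consecutive jumps and
compares with ⟨s′⟩ = 2·p_A·p_B·n, σ_s′ = √(p_A·p_B·n) (the conventional
n-form; the exact pair count n−1 is available and differs by O(1/n)),
reporting the one-sided normal tail of the deficit — a deficit beyond 2σ
(tail ≈ 0.023) indicates state retention without locating specific dwells.

## Synthetic data vs real data

The generators reproduce the features the estimators rely on: astigmatic
width encoding, photon-limited noise at ~2 photons/pixel background,
Brownian statistics, Markov state switching, the 100–400 photon signal
range. They do not reproduce dipole emission patterns, aberrations and
field-dependent PSFs, autofluorescent structured background, bleaching and
blinking, stage settling/hysteresis, or anomalous (non-Markov) diffusion.
Passing tests therefore demonstrate the correctness of the computation
chain and its statistical calibration under the stated model — not
robustness to every instrument non-ideality. Problem sizes in the test
suite and acceptance script (e.g. 10 trajectories × 300 jumps, 20 seed
replicates, 100 feedback episodes of 1000 frames, a retention scan capped
at 12 µm²/s) were chosen as the smallest sets at which the Monte-Carlo
standard errors are well below the tolerances being checked.
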