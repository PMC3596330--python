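# Methods

This note documents the models, conventions and parameter choices behind
`cardiomap`, in enough detail to interpret what its tests do — and do not —
demonstrate about real recordings.

## Action-potential template

A beat is parameterized by the resting/baseline potential (RMP, mV), the
action-potential amplitude (APA, mV), the upstroke duration (ms), and four
APD anchors: the times from activation to 20/50/70/90 % repolarization.

* **Upstroke.** A linear ramp from baseline to peak. Two consequences drive
  this choice. First, the maximal rise of the normalized amplitude is
  exactly `100 / t_upstroke` %APA/ms, and a forward difference across any
  window fully inside a linear segment equals the true slope — so the
  ground-truth upstroke velocity is recovered *exactly* at any sampling
  interval up to half the ramp duration, independent of sampling phase.
  Second, it makes the activation-time convention explicit: on a linear
  ramp the "time of maximal upstroke velocity" is the whole ramp, and the
  detector resolves the tie to the **ramp midpoint** (plateau-centered
  refinement, below). APD anchors are therefore referenced to mid-upstroke.
* **Repolarization.** A monotone piecewise-cubic (PCHIP) curve through the
  anchor points `(APD_f, 1 − f/100)` on the normalized 0–1 scale, extended
  to full repolarization at `APD90 + max(APD90 − APD70, 2 ms)`. PCHIP
  through decreasing knots is non-increasing, so APD monotonicity
  (APD20 < APD50 < APD70 < APD90) holds by construction whenever the
  anchors are valid. Anchors must be strictly increasing and larger than
  the upstroke duration; violations raise a parameter error.

## Group presets

Ground-truth values for the three preparations (RMP/MDP, APD anchors,
upstroke velocity, conduction velocity, anisotropy ratio, acquisition
interval, spontaneous cycle length and spontaneous fraction) are the
published group means for organ explant cultures, freshly isolated tissue
and monolayers. Two preset values are not published and were fixed once as
plausible choices: the monolayer APD20/APD50 (40 and 95 ms, a long-plateau
shape consistent with the published APD70/APD90 of 134.0/230.8 ms) and the
monolayer upstroke duration (4 ms; monolayer upstroke velocity was not
measurable at the 2 ms acquisition interval, and neither is it here — the
measurement deliberately raises a not-measurable error above 1 ms
sampling). APA defaults to 100 mV for all groups; every normalized
measurement is amplitude-invariant, so this only sets the mV scale of
synthetic traces.

## Intracellular trace model

* **Paced mode:** stimuli at a fixed cycle length; each stimulus that
  passes the refractory rule (below) emits one template beat at zero
  latency. The default 100 ms pre-stimulus segment gives the analysis a
  clean leading diastole.
* **Spontaneous mode:** diastole ramps linearly from the MDP at the
  configured phase-4 slope; when it reaches MDP + 0.1·APA the beat takes
  off from the matching point of the template upstroke, keeping the
  waveform continuous. The emergent cycle length is
  `ramp time + beat duration`; `slope_for_cycle_length` inverts this so a
  preset's published spontaneous cycle length can be dialed in directly.
  The 0.1·APA takeoff threshold is a modeling convenience, not a claim
  about pacemaker physiology.
* **Capture rule:** a stimulus elicits a beat iff the time since the last
  elicited beat is ≥ ERP, with ERP defaulting to APD90 + 20 ms. This
  refractory caricature reproduces the qualitative ordering of 1:1 capture
  loss across cycle lengths (monolayers, with their long APD90, lose
  capture near 250 ms; the tissue presets near 140 ms) without any ionic
  modeling. It produces clean 2:1 patterns, never Wenckebach-like ones.

## Optical movie model

Per-pixel activation times are the anisotropic-eikonal solution for
constant velocities on a uniform sheet: for a plane wave entering along the
fiber axis, `t = (x·û)/v(θ)` with the elliptical directional speed
`v(θ) = [(cos Δ/v_L)² + (sin Δ/v_T)²]^{-1/2}`; for a point stimulus,
`t = √((ξ/v_L)² + (η/v_T)²)` in fiber-aligned coordinates, with
`v_T = v_L / AR`. Pixel pitch defaults to 0.01 cm (a 1 cm × 1 cm field of
view for the 100 × 100 grid); it is metadata, never hard-coded in the
analysis. Each pixel's fluorescence is the template shifted by its
activation time, mapped to arbitrary units with a per-pixel gain jittered
uniformly by ±10 % and a jittered baseline offset (forcing the analysis to
normalize per pixel), synthesized on a 0.1 ms internal grid and decimated
to the camera interval (1 or 2 ms) by frame averaging — a camera-integration
model that smooths the upstroke the way a real sensor does. Gaussian noise
(SD expressed as a fraction of APA) is added per pixel per frame after
decimation. The generator refuses records too short for the wave to
traverse the grid.

Not modeled, deliberately: ionic/monodomain dynamics, wavefront curvature
and collisions, dye photophysics and photobleaching, motion artifacts,
out-of-plane (3-D) wavefronts. The last is the most consequential for real
data — epicardial optical mapping underestimates CV when wavefronts are not
parallel to the imaged surface — so recovery results here bound estimator
error, not biological measurement error.

## Analysis conventions

* Coordinates are 0-based `(row, col)`; angles are measured from the +x
  (column) axis toward +y (rows); windows are half-open; times in ms,
  distances in cm, intracellular voltages in mV.
* **Beat detection:** maxima of the (optionally Savitzky–Golay-smoothed,
  window 5, order 2; off by default) first difference above a threshold
  defaulting to 10 % of the global maximal derivative, with a 50 ms
  refractory between accepted activations. A beat with no stimulus in the
  preceding 20 ms marks the trace spontaneous; with no stimulus channel,
  any beat does.
* **Activation refinement:** the discrete derivative maximum is refined by
  a parabolic fit through the three surrounding samples, clipped to half a
  sample; exact ties with neighbours (noise-free linear ramps) resolve to
  the plateau center. Refinement matters: at 1–2 ms sampling and 100-pixel
  scale, unrefined activation times would quantize CV coarsely.
* **Diastole:** per diastolic interval, MDP = minimum voltage, slope =
  least-squares fit over the 50 ms window starting at the MDP (an endpoint
  method is available; on noise-free ramps they agree). Intervals whose
  MDP sits closer than 50 ms to the next upstroke are skipped with a
  warning. The phase-4 flag tests `median slope ≥ 5 mV/s` with a 1e-9
  epsilon so an exactly-5 mV/s ramp lands on the inclusive side of the
  float round-off. Reported potential: mean MDP when flagged, else the RMP
  (mean over the final 50 ms before each upstroke). Optical traces are
  rejected (uncalibrated units).
* **Normalization:** affine map per beat sending the median of the 20 ms
  pre-upstroke baseline to 0 and the beat peak to 100; idempotent, and it
  rejects beats whose amplitude is under 5× the baseline noise SD. All APD
  and upstroke measurements are invariant under affine rescaling of the
  raw trace.
* **APD:** time from the activation reference to the first downward,
  linearly interpolated crossing of `100 − f` %APA. An uncrossed level
  raises an explicit unmeasurable-APD error rather than silently dropping.
* **Movie preprocessing:** pixels are kept when their amplitude exceeds 5×
  a robust (median-absolute-deviation) temporal noise SD and 5 % of the
  in-mask median amplitude; each surviving pixel is normalized 0–100 once
  per record from a robust baseline (pre-stimulus median) and peak.
  Activation detection is affine-invariant per pixel, so record-level and
  per-beat normalization give identical maps; per-beat normalization is
  used on the trace path. An optional 3×3 spatial median filter changes
  noise-free activation times by less than one sample.
* **Activation map:** per-pixel time of maximal temporal derivative within
  the beat window, sub-sample refined; pixels below 20 % of the
  99th-percentile in-mask peak derivative are undefined; a map with more
  than half its masked pixels undefined is invalid. Times are relative to
  the stimulus when recorded. The detector's constant offset (half the
  upstroke plus the integration shift) cancels in every difference-based
  quantity (CV, AR, isochrone spacing); oracle tests therefore align maps
  at the earliest-activated pixel.
* **Two-site CV:** Euclidean distance over activation-time difference
  between two sites on a line along the activation gradient (i.e.
  perpendicular to the isochrones). In auto mode the pair lies along the
  mask-mean gradient direction through the map centroid, as far apart as
  the mask allows (≥ 20 pixels); misalignment with the gradient beyond 15°
  warns, equal activation times raise an undefined-velocity error.
* **Anisotropy:** CV is measured along rays from the stimulus site every
  5° (the step must divide 90°); each ray uses the innermost defined pixel
  beyond 10 px and the outermost defined pixel, requiring ≥ 20 px
  separation, averaging the two opposite half-rays. AR =
  CV(θ_max)/CV(θ_max + 90°) ≥ 1 by construction since θ_max maximizes the
  scanned profile. An ellipse fit to a single isochrone would be an
  alternative; the directional scan was chosen because it yields the full
  CV-vs-angle profile and degrades gracefully under masking.
* **Capture:** a stimulus is propagated if an activation follows within
  50 ms (tolerating conduction delay); the first two stimuli are excluded
  as the rate-adaptation transient; fewer than 4 stimuli is an error.
  Both window and exclusion are package choices.
* **Statistics:** mean ± SEM (sample SD, n−1); unpaired equal-variance
  Student's t for two groups, one-way ANOVA for three or more; Pearson χ²
  without continuity correction, switching to Fisher's exact (2×2) when
  any expected count is below 5; two-sided throughout, significance fixed
  at p < 0.05, no multiple-testing correction (pairwise comparisons are
  reported as-is, as in the summary tables this mirrors). Percentages are
  rendered with round-half-up (1/6 → 17 %), matching printed tables.

## Recovery studies and problem sizes

The acceptance script and the heavy tests use 20 seeded movies per
condition on the full 100 × 100 grid at the preset acquisition interval
(1 ms tissue, 2 ms monolayer) with noise SD 0.05·APA and a 30° fiber angle
(off-axis, and on the 5° scan grid so angular discretization does not
inflate AR errors for the anisotropic presets). Plane waves are used for
the two-site CV studies, central point stimuli for the anisotropy scans.
One movie costs ~1–2 s to synthesize and analyze; the full recovery suite
runs in a few minutes on one CPU. Unit tests use smaller grids where the
full field adds nothing.

Measured behavior on noise-free movies: activation maps match the eikonal
ground truth to ≤ 0.5 sample everywhere, recovered CV and AR match the
generator to three significant figures, and APDs measured at the native
template resolution reproduce the anchors within 0.5 ms (within 2 ms at
1–2 ms sampling, the residual being interpolation error on the curved
repolarization). Under the 5 % noise condition the 20-seed mean CV bias is
well under 5 % and the AR bias under 0.03; AR is slightly positively
biased because θ_max is an argmax over a noisy profile.

## Known limitations

* The generator's diastole is exactly linear and its noise i.i.d.
  Gaussian; real phase-4 depolarization is curved and real optical noise
  is correlated (shot noise, dye heterogeneity). Passing recovery tests
  shows the estimators are correct under the stated model, not that they
  are robust to every artifact of real recordings.
* The first-downward-crossing APD rule is noise-sensitive on slow
  repolarization tails (it biases early); the per-beat values in noisy
  demos show this. Smoothing before crossing detection is available but
  off by default to keep the noise-free path exact.
* The MDP is a minimum statistic and is negatively biased under noise
  (visible as ~0.5 mV at 0.5 mV trace noise).
* The capture model is a single-ERP rule: no restitution, no latency
  growth near the refractory boundary.
* Fisher's exact and χ² disagree by up to ~0.09 in mid-range p at cell
  counts near 50; the χ²-vs-Fisher consistency property is only asserted
  where the asymptotics have converged (small p, or much larger counts).
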