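# Methods

This note documents the models, estimators and numerical choices behind
`exotirf`, and what the synthetic-data tests do and do not establish about
real recordings.

## Vesicle state machine

Each ground-truth event carries a cargo amount `c` (relative fluorophore
units, drawn from N(500, 75²) clipped to [200, 900]; no absolute photon
calibration is attempted). The vesicle appears in the evanescent field
`appear_lead_s = 2 s` before fusion (mCherry visible, SEP quenched). SEP
fluorescence is the cargo in the vesicle times a Hill sigmoid of lumenal pH
with unit slope, φ(pH) = 1/(1 + 10^(pKa − pH)), with pKa 7.1, pH 7.4 while
the pore is open (and for released surface receptors) and pH 5.5 in the
resting lumen — literature-typical superecliptic-pHluorin photophysics.
The pore stays open `pore_open_s = 0.3 s` per opening.

- **Transient**: full release at fusion. The released pool's *spot*
  amplitude decays exponentially with `transient_release_halflife_s = 2 s`;
  lateral diffusion is not solved explicitly — the trace analysis fits
  single exponentials, so an exponential released-pool model keeps the
  forward model and the estimator on the same footing.
- **Persistent (control)**: the pore closes with the cargo retained and the
  lumen reacidifies; fluorescence relaxes exponentially toward the quenched
  level with `persistent_decay_halflife_s = 17 s`. Release at the first
  opening is zero for plain persistent events: the slow control decay is
  modelled as reacidification without release, which is what makes it a
  clean single exponential. (A 50% fast released component in every
  persistent trace would make any single-exponential fit recover ~7.5 s
  instead of 17 s; we verified this numerically before fixing the design.)
- **Kiss-and-run pair**: as persistent, but `partial_release_fraction =
  0.5` of the cargo is released at the first opening (the released half
  decays fast at the spot, producing the peak → partial drop → slow decay
  shape) and the remainder at a reopening `4 s + Exp(4 s)` later (mean 8 s,
  always > 4 s). The second event of a pair is a separate ground-truth row
  sharing the site.
- **Bafilomycin**: reacidification is disabled — the closed vesicle stays
  neutral (plateau) until a final full release (dwell `4 s + Exp(4 s)`)
  followed by the fast decay. Event frequencies are left essentially
  unchanged (persistent-fraction multiplier 0.95).

mCherry spot amplitude equals the vesicle content — pH independent,
stepping down only at release instants — so cargo conservation
(mCherry spot + cumulative released = c) holds exactly before noise and
bleaching. Released receptors additionally contribute a small, wide
surround offset (`surround_gain = 0.1` per released unit) that disperses
with a 25 s half-life; a permanent offset would accumulate over a movie and
mask half of the photobleaching trend.

Condition multipliers on (event count, persistent fraction): basal (1, 1),
KCl (2, 2.24 — persistent fraction ~22%), A23187 (1.5, 1.8), bafilomycin
(1, 0.95, reacidification off), cycloheximide and dyngo (1, 1). Decay
kinetics are identical across conditions.

## Rendering and noise

Movies default to 256×256 px at 0.16 µm/px (standard for a 100×, 16-µm
EMCCD pixel), 10 Hz, 60 s. Events land uniformly on a synthetic neuron
mask grown greedily (highest-potential frontier pixel first) over a
soma-plus-2–4-tapering-processes potential field; growth guarantees a
connected mask and, when requested, an exact foreground pixel count. Spots
are Gaussians with σ = 1.5 px; surround offsets use 3× that width. A
multiplicative ramp removes `bleach_fraction` (default 5%, realistic range
2–10%) of all intensity by the last frame; then Poisson shot noise (gain 1)
on top of a background of 100 counts plus Gaussian read noise (SD 3). The
evanescent-field depth profile is not modelled; vesicle approach appears
only as the mCherry pre-fusion step.

Amplitude scales were fixed a priori from the 2×background dwell rule (see
below): with peak ≈ φ(7.4)·c ≈ 333 counts over B = 100, a transient event
crosses 2B ~1–3 s after its peak and a persistent one ~15–25 s after, so
the 4-s boundary separates the regimes with margin on both sides.

## Detection

Frames are smoothed with a σ = 1.5 px Gaussian; a 2-frame forward
difference is thresholded at 5× a robust noise scale and candidate pixels
must be spatial local maxima. Two additions beyond the basic operator were
necessary and are part of the package's design:

- the threshold uses the *maximum* of the global MAD-based SD and a
  per-pixel temporal MAD — shot noise scales with intensity, and a global
  threshold fires continuously on top of bright persistent spots;
- the rise must persist into the next difference window (a genuine step
  occupies two 2-frame windows; single-frame Poisson spikes do not).

Candidates at the same site (1 µm² neighborhood) merge while contiguous in
time (`min_separation_s = 0.3 s` ≈ one rise); an independent
supra-threshold rise later at the same site is a separate detection, which
is what makes consecutive events countable. With defaults this gives
recall ≈ 0.98, precision ≈ 1.0 on basal movies and < 1 false positive per
noise-only movie. Weak second openings of kiss-and-run pairs (small SEP
jump when the reopening comes early in reacidification) are the main
missed detections.

## Traces, photometry and rise times

`extract_trace` returns the per-frame maximum of the 4 µm² box (13×13 px
at 0.16 µm/px; odd side nearest the requested area) and the mean of the
16 µm² box (25×25) minus the inner box; the background level B is the
pre-onset median of the spot trace (10 frames, minimum 3). The raw ROI
maximum reproduces a noiseless spot amplitude exactly, but on noisy data
its expectation has a decay-dependent floor (the maximum over ~170 noise
pixels) that biases fitted transient half-lives ~17% low. The pipeline
therefore uses matched-filter photometry — a σ = 1 px Gaussian before the
maximum — and restricts decay fits to the trace segment above
baseline + 15% of peak amplitude; both choices are exposed as parameters
and the raw definition remains the function default.

Rise times are 10–90% with linear interpolation between frames, measured
against the local pre-onset level (median of the 3 frames before onset)
so an earlier event in the same ROI does not stretch the apparent rise; a
one-frame step therefore reads 0.08 s at 10 Hz — resolution-limited, and
below the 0.3 s bound expected for instantaneous fusion. The pipeline
searches the peak within 0.5 s of the detected onset (fusions are
one-frame steps); the function default window is 2 s so slower ramps
measure correctly.

## Decay model and classification

The fit model is a plateau followed by one-phase decay,
F(t) = F0 (t < t0); (F0 − B)·e^(−k(t−t0)) + B (t ≥ t0), t½ = ln2/k exactly.
t0 is multi-started on a 0.5 s grid over the first half of the post-peak
window and refined by bounded scalar minimization (xatol 1 ms); for each
t0, (F0, k, B) come from bounded least squares seeded by a log-linear
regression. A fit is unconverged when k sits at its lower bound or the
decay amplitude F0 − B is negligible (constant traces). On noiseless data
the fitter recovers generating parameters to < 1% and plateau ends to
within one frame.

Classification follows the dwell rule: dwell = time from the *initial*
maximum (first frame within 90% of peak — on a noisy plateau the argmax
lands anywhere) until the 3-frame-median-smoothed trace first falls below
2× background. Dwell ≤ 4 s ⇒ transient; longer ⇒ persistent; a persistent
event whose post-peak trace prefers the delayed-plateau model over an
immediate decay by ΔBIC > 6, with t0 > 1 s and post-plateau t½ < 6 s, is
biphasic-persistent (the bafilomycin signature; 100% of simulated
bafilomycin traces and 0% of control ones at 5% noise). Right-censored
traces (never below 2B) count as persistent only when the observation
window exceeds the 4 s boundary; shorter censored windows are
`unclassified` — with movie-end events forced into the persistent class, a
pooled basal run reads ~13% persistent instead of ~9.8%. The 2×B rule is
inherently amplitude-dependent (a dimmer event crosses 2B sooner); the
simulator's amplitude range keeps misclassification below ~1% of events,
but this dependence is a property of the rule, not of the implementation.

## Spatial null model

`estimate_probability` places N events i.i.d. uniform on the foreground of
a threshold mask, uses the placement index as the (uniformly random) time
order, marks round(0.1·N) events at random ranks persistent (Bernoulli
labelling available), and scores a replicate when some persistent event
has a strictly later event inside an s×s-pixel window anchored on it
(offsets −⌊s/2⌋ … ⌈s/2⌉−1; s = 1 is the same pixel). The 1 µm² window is
realized as the 2×2-pixel block, the unique choice consistent with ≈ 0.02
at N = 40 on a 15,318-pixel mask (closed form 1 − (1 − 4/M)^78 = 0.0202;
the Monte Carlo gives 0.0204 ± 0.0004 at 10⁵ replicates — window pixels
falling off the mask are simply never hit, costing ~1% coverage on this
geometry). The estimator is vectorized over replicates; a scalar reference
implementation is kept for the exhaustive-enumeration oracle (M ≤ 12,
N ≤ 3). Monte Carlo SE is √(p(1−p)/R). No clustering null or edge
correction is attempted.

Observed consecutive-event pairing searches, per persistent event, for any
later event within a 1 µm square at acquisition pitch (default gap: the
rest of the movie) and is computed per cell. On ground-truth tables it
recovers the generator's pair fraction plus a small random-co-occurrence
floor (~2–3% at ~20k-pixel masks with 40 events) — the same floor the null
model quantifies. Reopenings that fall outside the movie revert the pair
to a plain persistent event, so realized pair fractions run slightly below
the nominal 0.15, mirroring the censoring any fixed-length recording
imposes.

## Group statistics

`compare_groups` is the classical pooled-variance unpaired two-tailed
Student's t-test, written from the textbook formulas (Welch by flag), with
D'Agostino–Pearson K² normality per group (n ≥ 8; skipped with a warning
otherwise), both cross-checked against independent references to 1e−10 in
the tests. The statistical unit is the cell; no multiple-testing
correction is applied, and the report says so.

## What the synthetic tests do not show

The generator draws fusions as instantaneous steps with exponential
decays, uniform event placement, stationary background and
spatially-uncorrelated noise. Passing tests therefore demonstrate the
*estimators'* correctness and calibration under the stated acquisition
regime, not robustness to focus drift, lateral cell movement, vesicle
motion before fusion, spatially structured autofluorescence, or
non-exponential dispersal — all of which real recordings contain.
Problem sizes in the test and acceptance runs (10 movies of ~40 events,
10⁵ null-model replicates, 200 traces per kinetic regime) were chosen to
keep Monte Carlo error comfortably inside the stated tolerances.
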