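# Methods

This note documents the models, estimators and numerical choices behind
`laminargamma`, and what the synthetic-column generator does and does not
emulate.

## Signals and conventions

Time is measured in milliseconds from trial start with half-open windows
`[start, end)`; channel 0 is the most superficial contact and depth grows
downward; sinks are negative and sources positive in every CSD. Derived
signals (LFP, ESA, CSD) are sampled at 1 kHz. A trial consists of a
1,050-ms baseline, stimulus onset, a 520-ms static period and contiguous
1,000-ms morph cycles (MCs); analyses use MC2 start to the analysis end,
which is 150 ms before the lever release whenever the release falls inside
that window.

## Preprocessing

* **LFP** — zero-phase low-pass FIR (pass < 160 Hz, stop 300 Hz, 80 dB as a
  single-pass spec), then integer decimation to 1 kHz. The low-pass stop
  band (300 Hz) is below the decimated Nyquist (500 Hz), so no further
  anti-aliasing stage is needed.
* **ESA** (entire spiking activity) — zero-phase high-pass (pass > 400 Hz,
  stop 300 Hz, 80 dB), full-wave rectification, then the LFP low-pass and
  the same decimation. ESA is a continuous measure of population spiking
  that avoids spike thresholding.

Filters are Kaiser-window FIR designs meeting the (pass, stop,
attenuation) contract as single-pass specifications; forward–backward
application doubles the stopband attenuation and removes group delay.
Because the Kaiser design ties passband ripple to stopband attenuation, a
low suppression spec (the 20 dB gamma band-pass) would ripple the
passband by ±10 %; the design attenuation is therefore floored at 40 dB,
which exceeds every stated suppression while keeping passband ripple
below 1 %. Trials are reflect-padded by three filter lengths before
filtering and trimmed afterward.

## Spline inverse CSD

The forward model assumes current sources uniformly distributed over
stacked cylindrical discs (radius R = 500 µm) in an isotropic medium of
conductivity σ = 0.4 S/m, with the CSD varying along depth as a natural
cubic spline through the electrode depths and vanishing beyond the end
knots. The potential per unit (CSD × thickness) at depth offset dz is

    k(dz) = (1 / 2σ) (√(dz² + R²) − |dz|).

The forward matrix integrates this kernel against the spline basis on a
5-µm quadrature grid (halving the step changes the matrix by < 0.1 %);
inversion solves the square system per time sample. Depth profiles are
smoothed per time sample with a Gaussian (SD 200 µm) truncated to half
the 1,000-µm window and renormalized to unit sum, including at the
edges. With potentials in volts the CSD comes out in A/m³. No diagonal
(electrode-noise) regularization is applied by default.

An important structural limitation drives two pipeline choices below: the
spline model cannot represent sources below the last contact or above the
first, so any physical current near the probe ends is squeezed into the
end knots.

## Layer identification

The layer-III/IV border is first estimated from the polarity inversion of
the stimulus-onset CSD (average LFP over the first 250 ms after onset of
all correct trials with a stimulus in the receptive field, inverted and
smoothed): scanning from the surface, the first channel whose 0–100 ms
mean is a source immediately followed by a sink marks the border at the
midpoint of that channel pair.

The estimate is refined with the baseline correlation matrix: per trial
the CSD is low-passed (pass ≤ 15 Hz, stop 20 Hz, 35 dB, zero phase) and
Pearson-correlated channel-by-channel over baseline+100 ms to
baseline−100 ms; the matrix entry is the median across trials. Two
deliberate choices differ from the most literal reading of the procedure:

1. **Unsmoothed CSD for the correlation matrix.** The 200-µm depth
   smoothing mixes each boundary channel with its neighbors across the
   border, which blurs the correlation-block edge; the unsmoothed inverted
   CSD keeps it sharp. Smoothing is used everywhere else.
2. **Local block contrast.** The refined border maximizes (mean
   within-block r − mean between-block r) evaluated on the sub-matrix of
   three channels on each side of the candidate split, among candidates
   within ±200 µm of the initial estimate (ties fall back to the initial
   estimate). A *global* two-block contrast is unsuitable: the column has
   three correlation blocks, and the global contrast increases
   monotonically as the split moves toward whichever *other* domain
   boundary decorrelates most strongly, so it systematically overshoots
   the III/IV border.

Channels above the border are supragranular (SG); channels from the
border to 0.5 mm below it are granular (G, border depth inclusive);
deeper channels are infragranular (IG).

## Spectral analysis

Complex Morlet wavelets Ψ(t, f₀) = A exp(−t²/2σ_t²) exp(2iπf₀t) with
σ_f = 1/(πσ_t), f₀/σ_f = 6 and unit energy (A = (σ_t√π)^−1/2), on a
geometric grid of 8 voices per octave from 5 to 160 Hz (41 frequencies).
PSD is |W|²/500 Hz averaged over the analysis window; samples within
3σ_t of a trial edge are excluded. The 1/f bias is corrected by
multiplying each PSD value by its wavelet's center frequency. The gamma
band defaults to the 42.5–130.5 Hz preset (the FWHM of the grand-mean
corrected PSD peak in the source data); `determine_gamma_band` computes
the FWHM band from a supplied mean PSD when automatic detection is
preferred, with the peak search bounded to 30–120 Hz. A second preset,
28–78 Hz, is used for the ESA domain-preference profiles.

## Hotspots

Per-channel gamma power is the band- and window-averaged corrected PSD of
the smoothed CSD, averaged over attend-in trials. Within each domain the
hotspot is the interior electrode strictly exceeding both same-domain
neighbors (ties: larger power, then more superficial). Failing that, a
peak hidden in the flank of a neighboring peak is detected from the first
differences g of the profile: an interior local minimum of g with g > 0
on both sides (rising flank) selects the first electrode of that pair; an
interior local maximum with g < 0 on both sides (falling flank) selects
the second. Flank orientation is decided purely from the signs of g
around the extremum, making the rule local and testable. If both searches
fail the domain has no hotspot. Hotspots must show ≥ 2.5× the baseline
gamma power during MCs 2/3 (boundary inclusive); ESA targets for
phase-coherence profiles are the ⌈2N/3⌉ channels with the strongest
attend-in ESA gamma power (ties toward superficial).

## Dominant gamma frequency

The hotspot CSD is band-passed 35–120 Hz (stops 25/140 Hz, 20 dB, zero
phase) and Hilbert-transformed; the amplitude envelope is smoothed with a
10-ms Gaussian (±3σ, unit sum). Within maximal runs of at least 40 ms in
which the envelope strictly exceeds its per-trial median over MC2/3,
troughs are located where the unwrapped phase crosses π + 2πk (linear
interpolation between samples; unwrapping prevents double counting at the
wrap boundary). Periods are successive trough differences within a run —
never across runs — and periods outside [1/120, 1/35] s are discarded.
The dominant frequency of a session × condition is the reciprocal of the
median period pooled across trials (even counts use the midpoint of the
two central periods).

The estimator runs on the **unsmoothed** inverted CSD: the tripolar depth
profile of a compact oscillator alternates sign across neighboring
channels, so the 200-µm smoothing partially cancels the local
oscillator while passing leakage from neighboring domains; on synthetic
columns this biased the granular estimate ≈ 1.5 Hz low, and the
unsmoothed signal removes the bias.

## Phase coherence

PhC(t, f) is the phase-locking value |⟨exp i(φ_a − φ_b)⟩| over trials,
with phases from the Morlet transforms, time-averaged over MC2/3, minus
the expected value for N trials with random phase relations,

    EV(N) = √π / (2√N),

the analytic expectation of the resultant length of N uniform unit
phasors (verified against a Monte-Carlo oracle to < 0.5 % down to
N = 10). Negative corrected values are retained so that averages stay
unbiased. CSD–ESA profiles pair each qualifying hotspot with the selected
ESA channels; CSD–CSD profiles exclude the reference electrode and both
immediate neighbors. Normalized domain preference divides each of the
three hotspots' gamma-band PhC values at a depth by their sum (negative
corrected values are clipped at zero before normalizing so the ratios
stay in [0, 1]). Attention contrasts take, per domain pair, the
other-domain channel with the highest attend-in gamma PhC as partner and
report the corrected gamma-band PhC in attend-in and attend-nearby.
Across sessions, profiles aligned on the border depth are combined by the
median, omitting depths covered by fewer than ⌈2S/3⌉ sessions.

## Statistics

Independent groups: Kruskal–Wallis omnibus (p < 0.05 gate), then Dunn's
pairwise rank z-tests (tie-corrected, two-sided at α = 0.05, no further
correction at this gating stage), then one-sided Wilcoxon rank-sum tests
for Dunn-significant pairs with the direction taken from the group
medians. Paired data: Friedman omnibus (plain signed-rank when only two
conditions), then two-sided signed-rank post-hocs with Tukey–Kramer
(studentized-range transform of the signed-rank z) or Bonferroni
correction; corrected p never falls below raw p. Animals are pooled only
when a rank-sum test cannot separate them (p > 0.05). Session-level
correlations use Pearson r with Bonferroni correction over the three
domain pairs.

## The synthetic column

The generator emulates, with known ground truth: three laminar gamma
oscillators; an evoked onset response; phase-locked spiking; shared
low-frequency baseline activity per domain; spatially correlated 1/f CSD
noise; and white sensor noise. Defaults (chosen once as the study
conditions; all configurable):

* **Probe** — 32 contacts at 100 µm. The spline iCSD cannot see below the
  last contact, so with a 16-contact span the deep oscillator's power
  leaks into the bottom channel; with 32 contacts the column occupies the
  upper half of the span and the deep channels record background, as in
  real penetrations. Layer-III/IV border at 650 µm; granular domain 500 µm
  thick.
* **Oscillators** — zero-integral Ricker (second-derivative-of-Gaussian)
  depth profiles, mean-subtracted on the simulation grid so discrete net
  current is exactly zero. A two-lobe sink/source pair was rejected
  because its power vanishes at its own center, which would put the
  gamma-power hotspot off the configured depth. Centers/SDs: SG 500/130,
  G 900/130 (border + 250 µm, the upper granular domain), IG 1400/130 µm;
  each center lies on an interior electrode of its domain even if the
  detected border is off by one pitch. Base frequencies 67.0, 70.7 and
  65.3 Hz; SG shifts +1.2/−0.7/−1.0 Hz for attend-in/nearby/away (the
  per-condition medians 68.2/66.3/66.0 Hz around the pooled 67.0 Hz), no
  attention effect on G or IG frequency. Instantaneous frequency drifts
  as an Ornstein–Uhlenbeck process (SD 2 Hz, τ = 200 ms); the amplitude
  envelope carries an OU modulation (depth 0.2, τ = 100 ms), is gated to
  20 % of its stimulus-period value during the baseline, and ramps up
  over 100 ms from 30 ms after stimulus onset.
* **Attention power gains** — amplitude factors √(1 + target/α_d) where
  the targets are the reported relative power increases (+38.1/+12.8 %
  SG, +28.5/+7.5 % G, +16.0/−4.1 % IG for attend-in/attend-nearby vs
  attend-away) and α_d is a per-domain dilution factor calibrated once at
  desk scale so that the *pipeline-measured* increase — which includes
  attention-independent background power at the hotspot — matches the
  target. The generator's purpose is that the measured study conditions,
  not the latent amplitudes, equal the stated values.
* **Evoked response** — derivative-of-Gaussian depth profile (width
  300 µm) centered on the border: source above, sink below; alpha-function
  time course with 30 ms onset latency and 50 ms decay.
* **Spiking** — inhomogeneous point process per channel with von-Mises
  rate modulation r(t) ∝ exp(κ_eff cos(φ_own − φ₀)), κ = 1.5 gated like
  the oscillators, weak cross-domain coupling 0.1, base rate 50 Hz with a
  sigmoid fall-off (floor 10 %) below a 1.6-mm cortex depth; events add a
  biphasic derivative-of-Gaussian waveform (σ = 0.2 ms, > 90 % of energy
  above 400 Hz).
* **Baseline activity** — per domain one shared < 12 Hz noise signal with
  a smoothed domain-indicator depth profile, present throughout the
  trial; plus weak independent per-channel low-frequency noise.
* **Noise** — 1/f CSD noise (unit-variance shaped spectrum, Gaussian
  spatial correlation 100 µm, amplitude 0.25 of the oscillator scale) and
  white sensor noise at 0.2 of the peak oscillatory LFP amplitude.
* **Rates and sizes** — raw rate 5 kHz (half the hardware rate of the
  source recordings; the ESA band 400–2,500 Hz survives and every filter
  contract remains exercisable at desk-scale runtimes), 20-µm simulation
  grid (≥ 5 points per pitch), 3 morph cycles, lever release 50–170 ms
  after MC3 (inside the behavioral response window, outside the analysis
  window, so the default MC2/3 window is trial-aligned; the 150-ms
  truncation rule is exercised in unit tests on explicit epochs).

Deterministic given the seed: trial order and every noise stream derive
from a `SeedSequence` spawned per trial.

### What the generator does not emulate

Biophysically detailed neurons, conduction delays, electrode impedance,
eye movements, behavioral errors (all simulated trials are correct;
the performance filter is exercised via the session metadata), saccade
or movement artifacts, non-stationarities across a session, and realistic
cross-frequency structure. Passing recovery tests on this generator shows
the pipeline correctly inverts the generative model the field's methods
assume — not that those assumptions hold in tissue.

## Problem sizes

Desk-scale defaults keep the full test suite and the acceptance script
within interactive budgets: acceptance runs use 100 attend-in trials for
frequency targets and 60 + 60 trials for attention-power targets; the
end-to-end suite fixture uses 60 trials per condition; border-recovery
checks use 20 seeds × 6 trials. At these sizes the dominant-frequency
median is stable to ≈ ±0.3 Hz and the measured power increases to
≈ ±2–4 percentage points across seeds.

## Known limitations

* The calibration of attention gains couples generator defaults to the
  default pipeline settings (gamma band preset, smoothing parameters); a
  materially different configuration would need recalibration.
* End-knot inversion artifacts inflate the top/bottom channel's power;
  the hotspot rule is immune (edge channels cannot be local peaks) but
  custom analyses should treat those channels with care.
* Dunn's test applies no multiplicity correction at its gating stage, and
  the interaction between the Dunn gate and the subsequent rank-sum stage
  is left exactly as narrated in the source procedure.
* The attend-nearby power calibration shares its domain's dilution factor
  with attend-in; measured nearby increases track their targets less
  tightly (±3 points).
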