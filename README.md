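# laminargamma

Laminar analysis of gamma-band oscillations in cortical columns recorded
with linear multielectrode probes.

Visual cortex is organized into vertical columns spanning six layers.
Whether the neurons of a column act as one ensemble with a single shared
gamma rhythm (30–100 Hz), or as several semi-independent laminar
ensembles, is a structural question about cortical computation — and it
is answerable from laminar recordings: distinct ensembles should show
depth-localized gamma generators with different peak frequencies,
different attentional modulation, and spiking that locks to its own
layer's rhythm more than to the others'. `laminargamma` implements the
full analysis chain needed to ask that question of trial-structured
broadband recordings from 16- or 32-contact laminar probes, plus a
synthetic cortical-column simulator with known ground truth for
validating every stage.

## The analysis chain

1. **LFP / ESA extraction** — zero-phase FIR filtering (LFP: < 160 Hz;
   ESA: > 400 Hz, rectified, low-passed) and decimation to 1 kHz. ESA
   ("entire spiking activity") is a threshold-free continuous measure of
   population spiking.
2. **Spline inverse current source density (iCSD)** — potentials are
   inverted to CSD assuming disc sources (R = 500 µm, σ = 0.4 S/m) and a
   cubic-spline depth profile:
   the kernel is φ(dz) = (1/2σ)(√(dz² + R²) − |dz|), inverted per time
   sample, then Gaussian-smoothed along depth (SD 200 µm).
3. **Layer identification** — the layer-III/IV border from the polarity
   inversion (source over sink) of the stimulus-onset CSD, refined with
   the block structure of low-frequency (< 15 Hz) baseline CSD
   correlations; channels are labelled supragranular (SG), granular
   (G, 0.5 mm below the border) and infragranular (IG).
4. **Gamma hotspots** — per-channel 1/f-corrected Morlet power
   (Ψ(t, f₀) with f₀/σ_f = 6, PSD = |W|²/500 Hz · f₀) in the gamma band
   (42.5–130.5 Hz); one hotspot electrode per domain via a discrete-peak
   rule with a gradient-based "hidden peak" fallback.
5. **Dominant gamma frequency** — band-pass 35–120 Hz, Hilbert phase and
   amplitude; within ≥ 40 ms episodes of above-median amplitude, cycle
   periods between successive phase-π troughs; the dominant frequency is
   the reciprocal of the pooled median period.
6. **Bias-corrected phase coherence (PhC)** — the phase-locking value
   PhC(t,f) = |N⁻¹ Σ_k exp i(φ_a,k − φ_b,k)| minus its random-phase
   expectation EV(N) = √π/(2√N); spectrolaminar CSD–ESA and CSD–CSD
   profiles, normalized domain-preference ratios, attention contrasts.
7. **Statistics** — Kruskal–Wallis + Dunn + one-sided rank-sum for
   independent groups; Friedman + signed-rank (Tukey–Kramer/Bonferroni)
   for paired conditions; rank-sum poolability checks; Pearson
   correlations with Bonferroni correction.

The package is organised statsmodels-style: build a `LaminarGammaModel`
from a `Session`, call `.fit()`, and read everything off the returned
`LaminarGammaResults` (`summary()`, CSV/JSON report writer, plotting
helpers in `laminargamma.plotting`).

## Worked example

Simulate a synthetic column (three laminar gamma oscillators at 67.0,
70.7 and 65.3 Hz with attention-dependent gains, an evoked onset
response, phase-locked spiking, correlated baseline activity, 1/f
noise) and run the full pipeline:

```python
from laminargamma import LaminarGammaModel, build_ground_truth, simulate_session

gt = build_ground_truth(seed=1)
session = simulate_session(gt, n_trials_per_condition=20)
results = LaminarGammaModel(session).fit()
print(results.summary())
```

Output (60 trials, ~2 minutes on one core):

```
Laminar gamma-oscillation analysis
==================================================
Trials: 60   channels: 32 @ 100 um   performance: 1.00
Gamma band: 42.5-130.5 Hz
Layer III/IV border: 650 um (initial 650 um)
Domains (channels): {'SG': 7, 'G': 5, 'IG': 20}

Hotspots:
  SG : channel 5 (500 um, local_peak, inclusion=True)
  G  : channel 9 (900 um, local_peak, inclusion=True)
  IG : channel 14 (1400 um, local_peak, inclusion=True)

Dominant gamma frequency (Hz):
condition  attend_away  attend_in  attend_nearby
domain
G                70.51      71.01          70.94
IG               65.38      65.00          65.22
SG               65.97      68.42          66.53

Gamma-power change vs attend-away (%):
condition  attend_in  attend_nearby
domain
G               31.4            9.0
IG              16.4           -5.7
SG              32.6           14.4

Mean normalized ESA PhC preference (reference x ESA domain):
esa_domain      G     IG     SG
reference
G           0.669  0.143  0.154
IG          0.177  0.550  0.047
SG          0.155  0.307  0.799

Attention PhC contrast (hotspot/partner):
 pair  hotspot_channel  partner_channel  phc_attend_in  phc_attend_nearby  delta
SG/IG                5               13         0.0332             0.0254 0.0078
 G/SG                9                6         0.2636             0.2622 0.0014
 IG/G               14               11         0.3036             0.3032 0.0003
```

Reading it: the layer-III/IV border is recovered at its configured
650 µm; each laminar domain contains exactly one gamma-power hotspot, at
the configured oscillator depths (500/900/1400 µm). The granular rhythm
is the fastest (≈ 70.7 Hz vs ≈ 66 Hz above and below), attention toward
the receptive field raises the supragranular frequency by ≈ 2.5 Hz and
boosts gamma power most strongly in the supragranular domain, and the
spiking of each domain (rows of the preference table) locks mostly to
its own domain's rhythm — the signature of three distinct laminar
gamma networks.

A thin CLI wraps the same machinery:

```sh
laminargamma simulate --seed 1 --trials 20 --out /tmp/sess
laminargamma analyze /tmp/sess --out /tmp/report
```

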