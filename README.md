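# kpsignal

Bioelectrical signal analysis for kombucha–proteinoid (KP) composites —
bio-hybrid materials made of a kombucha zoogleal mat doped with proteinoid
microspheres that spike electrically and respond to neuron-like stimulation.
`kpsignal` is a tested, reusable implementation of the full transduction
pipeline: neuromorphic stimulus generation, synthetic multichannel
recordings with ground truth, spike detection and statistics, channel
coordination via mutual information, and associative-learning analysis.

## What it computes

**Stimulus generation.** The Izhikevich spiking-neuron model

```
dv/dt = 0.04 v² + 5v + 140 − u + I
du/dt = a(bv − u),          if v ≥ 30 mV: v ← c, u ← u + d
```

integrated with fixed-step forward Euler (default dt = 0.25 ms) over a
registry of 20 published firing regimes (tonic spiking, tonic bursting,
accommodation, …), plus a battery of piecewise-constant pulse protocols and
audio-to-voltage conversion (e.g. owl vocalizations resampled and rescaled
into >1000 mV stimuli).

**Synthetic recordings.** Seeded 1 sample/s multichannel voltage recordings
whose spike amplitude and period laws are solved to match reported
statistics (kombucha: amplitude mean 11.63 mV, sd 10.01; period mean
219.92 s, sd 52.05 on [51, 331] s; analogous proteinoid targets), with
shared-source channel coupling `y = ρx + (1−ρ)n`, ADC-style quantization,
and exact ground truth for every injected event.

**Spike analysis.** Robust threshold detection (events are local maxima
above `median + k·1.4826·MAD`), box-plot summaries (Hazen quantiles,
n−1 standard deviations) of amplitudes and inter-spike periods, and
per-channel voltage statistics.

**Coordination.** Plug-in histogram mutual information in bits,

```
I(X;Y) = Σ p(x,y) log₂[ p(x,y) / (p(x)p(y)) ]
```

with equal-width binning (default B = 10), marginal entropies H(X) on the
matrix diagonal, optional rank binning and Miller–Madow correction, and
maximum lagged cross-correlation.

**Association learning.** Hebbian weight updates `Δw_ij = ε·α_i·α_j`
accumulated over stimulus–response pattern pairs, analog-to-bitvector
digitization, and the Hopfield energy `E = −0.5 ΣΣ w_ij α_j α_i` evaluated
pointwise or as a 2-D activity landscape.

## Worked example

```python
import numpy as np
from kpsignal import detect_spikes, mi_matrix, spike_summary, \
    simulate_izhikevich, regime_params
from kpsignal.synthetic import SyntheticConfig, ChannelConfig, \
    kombucha_channel, generate_recording

# 1. A tonic-spiking stimulus at model rate
wf = simulate_izhikevich(regime_params("tonic spiking"), duration=1000, dt=0.25)
print(f"tonic spiking: {wf.spike_times.size} spikes, apex {wf.values.max():.1f} mV")

# 2. A synthetic 4-channel recording: one kombucha-like spiking channel,
#    three noise channels of which two are coupled at rho = 0.95
cfg = SyntheticConfig(
    channels=[kombucha_channel()] + [ChannelConfig(noise_std=5.0) for _ in range(3)],
    duration=22_000.0, fs=1.0, coupling=[(2, 3, 0.95)], seed=42)
rec, truth = generate_recording(cfg)

# 3. Detect and summarize spikes on the spiking channel
events = detect_spikes(rec.values[:, 0], fs=rec.fs, k=6.0, min_separation=30.0)
s = spike_summary(events)
print(f"detected {s.count} spikes (injected {truth.spike_times[0].size})")
print(f"amplitude quartiles: {s.amplitude.q1:.2f}, {s.amplitude.q2:.2f}, "
      f"{s.amplitude.q3:.2f} mV; mean {s.amplitude.mean:.2f} mV")
print(f"period mean {s.period.mean:.2f} s, sd {s.period.std:.2f} s")

# 4. Channel coordination
m = mi_matrix(rec, bins=10)
print(f"MI(ch3, ch4) = {m.values[2, 3]:.3f} bits;  "
      f"MI(ch1, ch2) = {m.values[0, 1]:.4f} bits")
```

prints

```
tonic spiking: 38 spikes, apex 30.0 mV
detected 102 spikes (injected 102)
amplitude quartiles: 5.58, 8.81, 12.46 mV; mean 10.90 mV
period mean 213.47 s, sd 55.50 s
MI(ch3, ch4) = 2.054 bits;  MI(ch1, ch2) = 0.0017 bits
```

The detector recovers every injected event; the sample quartiles sit near
the configured kombucha law; and the coupled pair shares ~2 bits while the
independent pair's MI is three orders of magnitude smaller — the
synchronized-pair vs. independent-pair contrast the MI matrix is built to
expose.

## Command line

The same stages are available as `kpsig` subcommands operating on
CSV/WAV/JSON/YAML files: `simulate`, `protocol`, `audio2stim`, `synth`,
`spikes`, `stats`, `mi`, `xcorr`, `hebbian`, `energy`. All honor `--seed`
and `--config` where applicable and write sidecar `.meta.json` files with
the resolved configuration.

```sh
kpsig synth --seed 7 --out rec.csv        # recording + rec.csv.truth.json
kpsig spikes --in rec.csv --out spikes.csv
kpsig mi --in rec.csv --bins 10 --out mi.csv --heatmap mi.png
```

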