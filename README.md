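# seismocrab

Analysis pipeline for **percussive substrate-borne (seismic) signalling in
fiddler-crab courtship**, recorded *in situ* with paired dual-band geophones.
Male fiddler crabs escalate their courtship from visual claw-waving to
percussive displays — body drops that strike the substrate with the carapace,
and drumming, rapid claw-on-carapace percussion transmitted into the ground.
This package provides, as a tested library plus narrative analysis scripts:

* **I/O and synchronisation** — velocity traces (WAV/CSV) from a close
  (10 cm) and a far (20–100 cm) geophone pair, each with a low- (4.5–160 Hz)
  and high-frequency (100–400 Hz) sensor at 1612 Hz; behaviour-event tables
  (point and state tags from a nine-behaviour ethogram); wind and morphology
  tables; tap-spike video–seismic offset detection.
* **Behaviour windowing** — the fixed 0.4 s analysis window (645 samples):
  point tag ±0.2 s, or the middle 0.4 s of a state event; full-event parsing
  with a 0.6 s buffer for underground drumming and 0.2 s otherwise.
* **Signal features** — absolute peak amplitude per channel; normalised
  energy E = (Σ v²)/2; summed close-pair energy; peak frequency from a
  continuous 4.5–400 Hz spectrum spliced from the two bands at 160 Hz.
* **Drumming rhythm** — the quarter-of-maximum spike detector with a
  ±100-reading dominance guard, inter-spike intervals (Δt), bout splitting
  at Δt > 0.3 s, and pooled median/IQR rhythm statistics.
* **Spectrogram classification** — Hamming-window spectrograms (window
  length 128 or 256 samples, 98% overlap) resized to 224×224, duplication
  balancing, stratified 10-fold cross-validation (repeated), and the odds
  ratio of correct classification relative to chance,
  OR = [p/(1−p)] / [p₀/(1−p₀)] with p₀ = 1/k.
* **Synthetic scenes** — seeded generator for drumming bouts (Δt ≈ 0.16 s,
  median eight beats, first/last spikes weakest), body drops, wind-dependent
  band-limited noise, and power-law distance attenuation, with an exact
  ground-truth ledger. The original field recordings are not public, so all
  end-to-end behaviour is validated by parameter recovery on these scenes.
* **Summaries** — morphology covariates (claw/carapace size products), the
  |r| ≥ 0.70 correlation screen, middle-90% trimming, the ±3 s wind mean,
  exclusion-rate arithmetic, interference flagging, and log–log attenuation /
  log-linear wind-noise regressions.

## Worked example

```python
import numpy as np
from seismocrab import (PlantedBehaviour, SceneConfig, gen_session,
                        extract_feature_window, extract_features,
                        extract_full_event, detect_spikes, split_bouts)

cfg = SceneConfig(duration=30.0, seed=3, events=[
    PlantedBehaviour("UGD", 5.0),       # underground drumming bout
    PlantedBehaviour("simWBD", 15.0),   # simultaneous wave and body drop
])
session, events, truth = gen_session(cfg)

f = extract_features(extract_feature_window(session, events[0]))
print(f"drumming window: peak {f.peak_amp_high:.2e} m/s, "
      f"energy {f.sum_norm_energy:.2e} (m/s)^2, peak {f.peak_frequency:.1f} Hz")

w = extract_full_event(session, events[0])
train = split_bouts(detect_spikes(w.segments["close_high"], session.fs))
print(f"bout: {train.bout_size} spikes, median dt {np.median(train.dts):.3f} s")
```

prints (seed 3):

```
drumming window: peak 3.26e-05 m/s, energy 1.34e-08 (m/s)^2, peak 122.5 Hz
bout: 8 spikes, median dt 0.163 s
```

The drumming window's peak velocity sits near the planted close-high median
(4.35e−5 m/s scaled by what the 0.4 s window catches), its energy dwarfs the
background (~1e−10), and the detector recovers all eight planted beats at the
planted ~0.16 s rhythm.

The numbered scripts under `analysis/` run the full story on a reference
scene — `01` simulates it, `02` extracts features per behaviour and checks
the drumming > body-drop > non-percussive energy ordering, `03` recovers the
drumming rhythm, `04` cross-validates the 3-group spectrogram classifier,
`05` recovers the planted attenuation exponent and wind-noise slope — each
writing its tables to `results/`.

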