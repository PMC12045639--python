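# Methods

## The measurement model

A geophone outputs voltage proportional to ground velocity; traces here are
stored as velocity in m/s (a `scale` factor at read time converts
volt-recorded files, e.g. a 23.4 or 33.8 V m⁻¹ s⁻¹ sensitivity). Each burrow
is monitored by a close pair at 10 cm and a far pair at 20–100 cm, each pair
holding a low- (4.5–160 Hz flat response) and a high-frequency (100–400 Hz)
sensor, all sampled at 1612 Hz. Time is seconds from session start; sample
index = round(t × fs), with half-sample values rounded away from zero so the
0.4 s analysis window is 645 samples (0.4 × 1612 = 644.8).

Behaviour tags come from video annotation: point events (waving, sequential
wave, sequential body drop, simultaneous wave-and-body-drop) carry one
timestamp; state events (aboveground/underground drumming, locomotion,
mud balling, conflict) carry start/stop. Video time is mapped to trace time
by a synchronisation tap — the largest absolute amplitude inside a search
window around the annotated tap, required to exceed 5× the window's median
absolute amplitude (the multiple is configurable; no published value
exists).

## Windows and features

Feature windows are always 0.4 s: tag ±0.2 s for point events, the middle
0.4 s (midpoint ±0.2 s — the anchor is a package choice; only "middle" is
specified upstream) for state events. Full-event parsing for spike analysis
spans the event plus a 0.6 s buffer for underground drumming (aural onset,
less precise) and 0.2 s otherwise; the buffer does not move the feature
window. Windows crossing a trace edge are rejected rather than zero-padded,
since padding deflates energy.

Features per window: absolute peak amplitude per close channel; normalised
energy E = (Σ v²)/2 per channel and summed over the close pair; natural-log
energy; and peak frequency from a merged spectrum — the low channel's FFT
magnitudes for 4.5–160 Hz spliced with the high channel's for >160–400 Hz on
the shared bin grid (Δf = fs/N ≈ 2.5 Hz at N = 645). The 160 Hz seam is
inclusive to the low channel. Magnitude, not power, feeds the argmax (the
argmax is identical either way); ties resolve to the lowest frequency; no
detrending or tapering is applied before the feature FFT (a mean-removal
flag exists). Bins below 4.5 Hz fall outside both sensors' response and are
discarded.

## Drumming-spike detection and rhythm

On the close high-frequency channel, sample i is a spike iff |v_i| ≥ ¼ of
the segment's maximum absolute amplitude and |v_i| strictly exceeds every
other sample within ±100 readings (0.062 s). Strictness means plateaus of
equal samples yield no spike; the guard window truncates at segment edges
and spikes within one guard of an edge are flagged. The ¼ threshold is
computed over the full tagged segment *before* bout splitting (detection
first, splitting second). Δt is defined for every spike except a bout's
first; gaps with Δt > 0.3 s split the train and the sub-bout with the most
spikes is kept (ties → earliest). IQRs use linear-interpolation quantiles
(Q3 − Q1).

## Spectrogram classification

Spectrograms use a Hamming window of 128 or 256 samples at 98% overlap; hop
= max(1, round(0.02 × wl)) → 3 or 5 samples; frames = floor((N − wl)/hop)+1
(173 or 78 at N = 645). The magnitude matrix is cropped to the band's
response rows, log-scaled, min–max normalised and bilinearly resized to
224×224 (operating on raw matrices replaces any plot-border cropping; an
all-zero matrix yields a flagged all-zero image). Rarer classes are balanced
by cyclic duplication up to the majority count.

Evaluation is stratified 10-fold cross-validation, repeated (default five
times), with balancing applied **inside training folds only** so no
duplicate of a test item reaches training; a `balance="before_split"` mode
reproduces whole-dataset balancing before splitting, which is how the
original analysis ordered these steps but risks leakage. For combined-band
classification the per-band image features are concatenated per sample.
Accuracy is the mean over folds and repeats; the odds ratio against chance
p₀ = 1/k is [p/(1−p)]/[p₀/(1−p₀)] — 1 exactly at chance and strictly
increasing in p.

The default classifier extracts fixed image features — 8×8 mean- and
max-pooled grids plus per-frame max/mean profiles (max pooling keeps the
few bright vertical stripes of sparse impulses visible) — and fits a
standardised multinomial logistic regression. Any estimator factory can be
passed as `model_spec`; a deep pretrained feature extractor is a pluggable
backend, not a dependency, because the pipeline and its evaluation
arithmetic are the reproducible content here, and no public weights or
recordings exist to anchor absolute field accuracies. Augmentation is an
off-by-default hook.

## Synthetic scenes

With no deposited recordings, the generator is the test bed, emulating the
reported signal phenomenology:

* **Impulse**: damped sinusoid, decay constant 10 ms, centre frequency drawn
  uniformly from 100–350 Hz, abrupt onset (broadband), unit peak.
* **Drumming bout**: default eight spikes (the observed median), intervals
  drawn N(0.16 s, 0.02 s) clipped to (0.05, 0.3) s — the split rule's domain
  — with first and last spikes at 0.6× the bout amplitude (the reported
  weakest-edge pattern) and ±8% amplitude jitter elsewhere.
* **Body drop**: one impulse centred in a 0.4 s window.
* **Amplitudes**: close-channel peaks default to the reported medians —
  drumming 3.6e−5 (low) / 4.35e−5 (high) m/s, body drop 1.05e−5 / 7.20e−6
  m/s. Channel assembly band-passes the raw waveform per sensor (zero-phase
  4th-order Butterworth; in-band gain within 1 dB, ≥20 dB an octave out),
  scales the close channel to the target peak, and attenuates the far
  channel.
* **Attenuation**: energy ∝ (d/d_ref)^(−α), amplitude × (d/d_ref)^(−α/2);
  α defaults to 2 (no functional form is published; a power law is the
  standard surface-wave assumption and the exponent is configurable).
* **Wind noise**: ideally band-limited Gaussian noise synthesised
  spectrally, so E[energy] is exact: log E[energy] = log(floor² N/2) +
  slope × wind. Defaults — floor 2e−7 m/s RMS, slope 0.35 per (m/s) — are
  placeholders for an unreported quantity, chosen so percussive signals
  dominate calm-weather noise as the field spectrograms show; they are not
  claims about the field site.
* Non-percussive behaviours plant event tags with no waveform (negligible
  seismic signature). One seeded generator drives all draws; sessions are
  bit-reproducible.

What the generator does **not** emulate: dispersive/elastodynamic
propagation, substrate heterogeneity, neighbouring-crab interference,
sensor self-noise spectra, or the within-crab repeated-measures correlation
structure of real colonies. Passing recovery tests therefore demonstrates
the pipeline's correctness on signals with the reported statistics, not
field-data classification performance.

## Recovery experiments and numerical choices

* **Detector score**: 200 seeded 8-spike bouts with additive Gaussian noise.
  SNR is defined as impulse peak over the *maximum* noise excursion: under a
  σ-based definition the ¼-max threshold (2.5σ at SNR 10) sits below the
  expected maximum of ~2000 Gaussian samples (≈3.9σ), so occasional false
  positives are unavoidable for any threshold detector and a
  perfect-detection regime only exists under the peak convention. A
  detection within 8 samples (≈ half a carrier period) of a planted index
  counts as that impulse, since noise can move the absolute maximum to an
  adjacent oscillation extremum of the same impulse.
* **Attenuation recovery**: 30 single-bout sessions, far pair drawn from
  {20, …, 100} cm, α = 2. Far-window energies are background-corrected by
  subtracting the mean energy of four behaviour-free windows from the same
  session before the log–log fit; without this the additive noise floor
  inflates far-distance energies and flattens the recovered exponent
  (≈ −1.8 for a planted −2). The fit is ordinary least squares of
  log(energy) on log(distance), slope ± SE.
* **Wind recovery**: 200 behaviour-free 0.4 s windows over 0–8 m/s; OLS of
  log(energy) on wind speed.
* **Pipeline check**: 60 windows per behavioural group at peak SNR 5
  (anchored to the weakest planted class, the body drop's 7.2e−6 m/s
  close-high amplitude, so every percussive event meets the ratio), combined
  bands, wl = 256, 10-fold CV. Problem sizes throughout are chosen to keep
  the full suite in single-digit minutes on one CPU while leaving the
  statistical criteria (2-SE coverage, ≥0.85 accuracy) well determined.
* **Quantiles** are linear-interpolation throughout (IQR, middle-90% trim:
  the closed [P5, P95] interval of the values — the upstream phrase
  "middle 90% of variance" is ambiguous between values and variance; values
  are used and the choice is configurable in spirit by calling numpy
  directly).
* The exclusion-rate denominator is the retained count (matching the
  published 3.8% = 311/8207 arithmetic). The interference flag (far-pair
  energy exceeding close-pair energy) is an automated surrogate for the
  original manual video screen and is labelled best-effort.

## Known limitations

* Absolute classification accuracies on real field data are out of reach by
  construction (no public recordings, no pretrained-weight replication);
  only the evaluation arithmetic and the pipeline's behaviour on synthetic
  scenes are validated.
* The spike detector inherits the ¼-max rule's segment dependence: adding
  silence changes nothing, but trimming a segment's loudest spike rescales
  the threshold for the rest.
* Overlapping concurrent state behaviours are analysed independently; no
  source separation is attempted.
* Mixed-model inference (behaviour/morphology/distance effects with burrow
  and crab random effects) is delegated to external statistics tooling; the
  package emits tidy tables keyed by burrow/crab id for that purpose.
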