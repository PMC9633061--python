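# callcat

Feature-based categorization of animal vocalizations, end to end:

1. **`callcat.calls`** — synthetic vocalization corpus: four call-category
   archetypes (two sharing long-term spectra but differing in syllable/ISI
   timing, two sharing envelopes but differing in spectral content), with
   per-exemplar jitter in F0, syllable durations and inter-syllable
   intervals; WAV + CSV-sidecar + JSON-manifest I/O.
2. **`callcat.cochleagram`** — spectrotemporal representation: gammatone
   filterbank on a 67-channel log CF grid (200 Hz – 20 kHz), envelope
   extraction, 1 kHz frame rate, optional power-law compression. The front
   end is pluggable (`register_front_end`).
3. **`callcat.manipulate`** — stimulus battery: additive noise at fixed
   SNR, onset truncation, phase-vocoder tempo change, duration-preserving
   F0 shift, temporal reversal, FIR low-pass, and ISI surgery (silent /
   within-category random / cross-category chimeric).
4. **`callcat.mif`** — the core model: random rectangular cochleagram
   patches scored by maximum normalized cross-correlation, per-patch
   detection thresholds chosen by mutual information, log-likelihood-ratio
   weights, greedy selection of compact minimally redundant ensembles
   (several feature-disjoint instantiations), weighted feature-detection
   responses, winner-take-all Go/No-go decisions with a stochastic
   guess/lapse stage.
5. **`callcat.spectrum`** — long-term-spectrum linear-SVM baseline with its
   own winner-take-all stage.
6. **`callcat.metrics`** — d′ with rate clamping, Weibull psychometric fits
   with lapse rate and d′-scale amplitude, model–behavior R²/MAE, trialwise
   logistic likelihood-ratio tests, catch-trial Go-rate comparisons.
7. **`callcat.experiments`** — trial-list builders for every paradigm
   (factorial or block designs, catch-trial composition), execution of a
   trial list against a model pair (each ensemble instantiation acts as one
   subject), and pooled summary tables.

## CLI

```bash
callcat generate-corpus --out corpus/ --seed 0
callcat train --corpus corpus/ --category chut --out models/chut --seed 0
callcat train --corpus corpus/ --category purr --out models/purr --seed 0
callcat manipulate --input corpus/chut-train-0.wav --output shifted.wav --kind f0 --parameter 100
callcat run --corpus corpus/ --target-model models/chut --distractor-model models/purr \
            --paradigm snr --target chut --distractor purr --out trials.csv
callcat analyze --trials trials.csv --out summary.csv
callcat report --summary summary.csv
```

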