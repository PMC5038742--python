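# stepfall

Bayesian detection of atomic movements — steps and falls — from a single
tri-axial accelerometer, plus a calibrated synthetic trace generator so
the whole pipeline is testable without any recordings.

## What it does

- **signal** — accelerometer streams in g units; gravity estimation by a
  centred 2-s moving average, projection into vertical / longitudinal
  dynamic components, and torso-location amplitude compensation.
- **features** — window max/min extrema; step features
  (f1 = vertical amplitude range, f2 = longitudinal max-minus-min time
  lag), fall features (|G| range and min-to-max lag in ms), and the raw
  axis triple at the |G| impact peak for fall classification.
- **model** — per-cadence Gaussian feature likelihoods (60/80/100
  steps/min), a two-sided exponential-tail null-class density, the
  cadence posterior and step probability, and peak-normalised Gaussian
  kernel scores for fall detection (threshold 0.1) and fall
  classification (classes c1/c2/c3).
- **detectors** — full-recording step detection with periodic
  miss-correction, and fall detection plus classification.
- **synthetic** — seeded generators of walks, falls and null activities
  whose extracted features follow the shipped calibration tables.
- **io / cli** — CSV time-series and event I/O, a versioned JSON model
  file, and a `stepfall` command-line interface.

## CLI

```sh
# synthesise a 20-step walk at 80 steps/min plus its ground-truth sidecar
stepfall simulate --walk --cadence 80 --steps 20 --seed 1 \
    --out walk.csv --truth-out walk.truth.csv

# detect steps (shipped calibration) and score against the ground truth
stepfall detect-steps walk.csv --out events.csv
stepfall eval --events events.csv --truth walk.truth.csv

# falls
stepfall simulate --fall --fall-class c1 --seed 7 --out fall.csv
stepfall detect-falls fall.csv --out fall_events.csv

# train a cadence model from labelled walking CSVs
stepfall train-steps --input 60=walk60.csv --input 80=walk80.csv \
    --input 100=walk100.csv --out model.json
```

Time-series CSVs use the header `t,ax,ay,az` (seconds / g; `--units
"m/s^2"` converts on read). Event CSVs are
`kind,time_s,score,label,inserted`; ground truth is `kind,time_s,label`.

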