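# usv44

Analysis pipeline for rat ultrasonic vocalization (USV) call tables, built
around the four-type threshold taxonomy that separates a high-frequency
(>32 kHz), long (>150 ms) call class from classic long/short 22-kHz and
short 50-kHz calls.

The package ingests per-call feature tables (onset, duration, peak
frequency, optional frequency contour) in Avisoft-like, DeepSqueak-like, or
its own native CSV dialect, and provides:

- **`calltable_io`** — domain types (`CallRecord`, `CallContour`,
  `SessionMeta`, `MotionSeries`) and lossless, unit-normalizing I/O.
- **`acoustics`** — spectrograms, peak frequency (argmax of the
  time-averaged spectrum over a call), contour mean power, and
  microphone-angle attenuation correction (+10 dB at 40 kHz vs 20 kHz by
  default).
- **`classify`** — the threshold classifier (strict `>32 kHz` / `>150 ms` /
  `>300 ms` boundaries), per-table counts, and per-inter-trial-interval
  (ITI) call-type profiles.
- **`subtypes`** — contour segmentation into constant-frequency elements at
  instantaneous jumps (>4 kHz within ≤10 ms), the 1/5th prefix/suffix
  trimming rule, the five-subtype categorization (flat / step up / step
  down / insert / complex), and element frequency-ratio statistics.
- **`sequences`** — bout segmentation (<320 ms silent gaps) and call-type
  transition count/probability matrices (all pairs or within-bout).
- **`clustering`** — DBSCAN on standardized (peak frequency, duration) with
  a k-distance-knee epsilon heuristic and silhouette reporting, plus
  contour-shape k-means with elbow-selected k and optional 2-D embedding.
- **`behavior`** — freezing scoring from motion-index series (threshold 18,
  ≥30-frame runs), 10-s-bin linkage of freezing to call emission, and
  call-nested freezing windows.
- **`simulate`** — a fully seeded synthetic cohort generator (call tables,
  contours, shock schedules, motion series) with planted class features,
  Markov type sequences, bout timing, 3:2 step ratios, rising per-ITI
  high-call share, and call-locked freezing, used as the test oracle.
- **`pipeline` / `cli`** — end-to-end orchestration with a JSON config and
  a reproducibility manifest.

## CLI

```bash
usv44 simulate --n-rats 8 --seed 7 --out cohort/
usv44 classify --in cohort/rat000_s7_calls.csv --out typed.csv --summary summary.json
usv44 subtypes --in typed.csv --contours cohort/rat000_s7_contours.csv --out subtyped.csv
usv44 transitions --in typed.csv --scope within_bout --max-gap-ms 320 --out transitions.json
usv44 cluster dbscan --in typed.csv --min-pts 150 --out clusters.json
usv44 cluster kmeans --in typed.csv --contours cohort/rat000_s7_contours.csv --seed 7 --out kmeans.json
usv44 freeze-link --calls typed.csv --motion cohort/rat000_s7_motion.csv \
    --meta cohort/rat000_s7_session.cfg --out bins.json
usv44 run --seed 7 --out results/          # full pipeline on a synthetic cohort
```

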