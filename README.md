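# feverwatch

Passive infrared fever surveillance at a doorway, end to end:

- **`feverwatch.synthgen`** — synthetic daily temperature recordings
  (9 Hz R1-max / R2-mean streams) with ground truth: non-homogeneous
  Poisson arrivals with an hourly profile, front/back passes, sub-second
  back passes, hot-object confounders, per-sample sensor noise, and a
  multi-week study generator whose weekly fever prevalence is linearly
  coupled to a synthetic weekly ARI (acute respiratory infection)
  incidence series.
- **`feverwatch.tti`** — temperature–time identification of persons:
  segment the continuous R1 stream into above-threshold runs (strictly
  > 33 °C), merge runs separated by ≤ 1 s, and keep segments whose peak
  lies in [33, 40] °C and whose duration is strictly longer than 1 s.
- **`feverwatch.acquisition`** — the alarm-driven single-frame capture
  path (trigger above 33 °C, capture 0.6 s later, rearm after a
  sub-threshold sample) and FTI person identification from front-of-head
  frames, with a ground-truth orientation oracle standing in for an
  image classifier. Also the camera/recorder rate model
  (27 FPS decimated to every third frame → 9 samples/s).
- **`feverwatch.epistats`** — daily/weekly counts, hourly histograms,
  mean/sd, fraction of detections above the 37.5 °C fever cut,
  Fisher–Pearson skewness, z-score normalization and Pearson correlation
  of weekly statistics against the ARI series.
- **`feverwatch.io`** / **`feverwatch.cli`** — CSV formats (recordings,
  detections, ARI, summaries), flat TOML scenario configs, and the
  `feverwatch` command line.

## CLI

```sh
# 4 simulated weeks of daily recordings + ground truth + ARI series
feverwatch simulate --weeks 4 --seed 1 --out sim/

# identify persons (TTI from the stream, FTI needs sim/truth.csv labels)
feverwatch detect --method both --in sim/ --out detections.csv

# aggregate and correlate
feverwatch summarize --in detections.csv --by week --out weekly.csv
feverwatch correlate --summaries weekly.csv --ari sim/ari.csv \
    --statistic frac_fever --out report.json
```

`simulate` echoes the scenario config into the output directory; a
custom scenario can be passed with `--config scenario.toml` (flat TOML,
keys as in `feverwatch.ScenarioConfig`).

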