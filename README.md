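# aisleep

Unsupervised, interpretable sleep staging from a single EEG channel.

For every 30-s epoch of an overnight recording (100 Hz, µV), the pipeline
computes a Welch power spectral density in dB, embeds the 0.2–30 Hz rows into
two dimensions with UMAP, and then carves out the five AASM stages with
competing *feature-weighted* Gaussian kernel density estimates over the
embedding:

1. **Open-eye Wake** — weights from gamma-band power (25–50 Hz), split by an
   Otsu threshold; epochs in the high-density region become Wake.
2. **N2N3** — the PSD is decomposed into fractal and oscillatory components
   (irregular-resampling auto-spectral analysis); a personalized fast-spindle
   band (night-specific peak ± 1 Hz, nearest 14 Hz) yields per-epoch spindle
   power, whose Gaussian-CDF weights drive two competing densities.
3. **N3** — slow oscillations (0.5–2 Hz, five amplitude/duration criteria)
   are detected on the band-passed signal; epochs dense in SO percentage are
   split into N3 vs Wake by proximity in the embedding, the rest of N2N3
   becomes N2.
4. **Closed-eye Wake** — oscillatory strength (std of the oscillatory PSD
   over 5–20 Hz) separates alpha-rich epochs from the remainder.
5. **N1 vs REM** — remaining epochs are hypothesized REM; short runs whose
   temporally smoothed stage curve sits closer to N1 are flipped.

Everything is testable offline: `aisleep.synthetic` generates ground-truthed
nights with stage-conditioned spectral content (1/f background, gamma bursts,
alpha rhythm, spindle packets, slow-oscillation trains, low-amplitude
mixed-frequency N1/REM).

## CLI

```sh
# generate a synthetic night (EDF + ground-truth hypnogram)
aisleep simulate --seed 0 --n-epochs 960 --out-edf night.edf --out-hypnogram truth.txt

# stage a recording (any standard EDF; channel selected by label)
aisleep stage --edf night.edf --channel "synthetic Fpz-Cz" \
    --out-hypnogram pred.txt --out-features features/ --seed 42

# score against a reference hypnogram (one stage token per line)
aisleep evaluate --ref truth.txt --pred pred.txt
aisleep evaluate --ref truth.txt --pred kmeans_labels.txt --align-clusters

# feature tables only
aisleep features --edf night.edf --channel "synthetic Fpz-Cz" --out features/
```

`stage` accepts `--config config.yaml` (keys mirror `aisleep.staging.StagingConfig`,
e.g. `welch.segment_s`, `umap.n_neighbors`, `density_fraction`) and
`--trim START END` to restrict to explicit bounds in seconds. The resolved
configuration is echoed next to every output hypnogram for provenance.

Hypnograms are single-column text, one token per 30-s epoch, with codes
0 Wake, 1 N1, 2 N2, 3 N3, 4 REM, 5 Unknown (tokens W/N1/N2/N3/REM also
accepted). A helper (`aisleep.signal_io.merge_rk_stages`) converts R&K
vocabularies (S3+S4 → N3, MOVEMENT/UNKNOWN dropped) for evaluation.

## Layout

```
src/aisleep/
  signal_io.py   EDF + hypnogram IO, 30-s epoch grid
  spectral.py    Welch PSD (dB), fractal/oscillatory decomposition, smoothing
  embedding.py   2-D UMAP embedding of PSD rows
  features.py    band power, Otsu, spindle band, slow oscillations, std_osc
  kde.py         weighted Gaussian KDE, Scott bandwidth, Gaussian fit/CDF
  staging.py     the five-step carving cascade and pipeline
  metrics.py     confusion matrix, accuracy/MF1/kappa, cluster alignment
  synthetic.py   ground-truthed synthetic night generator
  cli.py         command-line entry points
```
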