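# neuroindex

Tools for individualizing motor-imagery BCI setups from short resting EEG
recordings:

1. **Individual alpha frequency (IAF)** — estimated from the eyes-closed
   minus eyes-open power difference at the occipital channels O1/O2
   (Welch PSD, 4-s epochs); the IAF anchors two individualized 2-Hz alpha
   sub-bands, `(IAF-2, IAF)` and `(IAF, IAF+2)`.
2. **Neurophysiological aptitude index** — the central-channel (C3/C4) PSD
   is fitted with a constant + power-law + Gaussian-peak model; the index is
   the maximum elevation of the fitted model above its power-law component.
   When the fit degenerates to the power law, the fallback uses the raw PSD
   instead, and the method used is always recorded.
3. **Cardiac validation path** — a single-lead ECG is high-pass filtered at
   0.1 Hz, R peaks are found with the Pan-Tompkins detector, NN intervals
   are averaged and inverted into the cardiac frequency `s`, and the
   harmonic series `f_d(i) = s * 2**i` yields a theoretical alpha center at
   `i = 3` (8·s) to cross-check the EEG-derived IAF.

A seeded synthetic-data module (1/f EEG background, reactive occipital
alpha, sensorimotor peak, schematic ECG) makes every stage testable without
any external recordings.

## CLI

```sh
# full pipeline: report.json, iaf.png, predictor.png written to --out
neuroindex run --eo EO.txt --ec EC.txt --fs 128 [--ecg ECG.txt] [--out DIR] \
               [--map channels.tsv] [--config config.toml] [--no-figures]

# write synthetic fixture files (add --ecg for an ECG trace)
neuroindex synth --out-dir fixtures --seed 1 --duration 180 --fs 128
```

Recordings are delimited numeric text (comma, tab, or whitespace,
auto-sniffed) with an optional single header row of channel labels;
orientation is auto-resolved (the longer axis is time). Headerless
64-channel files use the shipped BioSemi 10/10 label table; other layouts
need a two-column `label<TAB>row-index` map via `--map`. A MAT-file
containing a single 2-D numeric array is also accepted through the library
API (`neuroindex.io_formats.read_mat_recording`).

All tunables (Welch epoch length/overlap/window, IAF search band, fit band,
one- vs two-peak model, fallback threshold, NN plausibility window) live in
a TOML config; the reference file with defaults is shipped at
`src/neuroindex/data/default_config.toml`.

## Library sketch

```python
from neuroindex import read_recording, welch_psd, estimate_iaf, fit_psd_model
from neuroindex.predictor import compute_predictor
from neuroindex.cardiac import analyze_ecg

ec = read_recording("EC.txt", sample_rate_hz=128)
eo = read_recording("EO.txt", sample_rate_hz=128)
iaf = estimate_iaf(welch_psd(ec), welch_psd(eo))          # iaf.iaf_hz, bands
fit = fit_psd_model(welch_psd(eo), "C3", iaf_hz=iaf.iaf_hz)
index, method = compute_predictor(fit, welch_psd(eo))
```

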