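# songscan

Automatic detection of animal songs in long field recordings, built as a
two-phase pipeline:

1. **Training phase** — a band-limited energy detector finds candidate
   songs inside a frequency band (default 1000–6100 Hz) and duration window
   (0.5–5 s); each candidate is measured into a 16-feature acoustic vector;
   manually (or synthetically) annotated candidates — class 0 = not the
   target species, classes 1–3 = target songs of increasing selection
   quality — are binarized to presence/absence and used to train an
   RBF-kernel SVM with a decade grid search over (gamma, cost).
2. **Testing phase** — new recordings are scanned with the same detector,
   candidates are classified by the trained SVM, and results are reported
   as presence flags, review selection tables, and calls-per-minute
   relative abundance, with mixed-model AIC comparison between sites.

Evaluation uses balanced accuracy, BAC = (P(A) + P(B)) / 2 × 100, over
repeated stratified 70/30 holdouts (default 1000 repetitions), plus ROC
AUC and a learning curve over training-data fractions 0.9 … 0.1.

Because no field recordings ship with the package, a synthetic-soundscape
generator (`songscan.synthetic`) produces audio with known ground truth:
trilled frequency-sweep target songs, sweep distractors, broadband noise,
and an optional constant narrowband "cricket" confound overlapping the
song band. Every stage of the pipeline is tested against these soundscapes
and against brute-force oracles.

## CLI

All commands accept `--config <json>`, `--seed <int>` and `--log-level`.

```bash
# training phase on a synthetic soundscape
songscan simulate --config cfg.json --out-wav scape.wav --out-truth truth.txt
songscan detect   --config cfg.json --audio scape.wav --truth truth.txt --out candidates.txt
songscan measure  --config cfg.json --audio scape.wav --selections candidates.txt --out features.csv
songscan train    --config cfg.json --features features.csv --tune --out model.pkl
songscan evaluate --config cfg.json --features features.csv --out eval.json
songscan learning-curve --config cfg.json --features features.csv --out curve.csv

# testing phase
songscan scan --config cfg.json --model model.pkl --out-dir scans/ --report scan.json new1.wav new2.wav
songscan abundance --report scan.json --metadata meta.csv --out abundance.csv
songscan compare-sites --abundance abundance.csv --out comparison.json
```

The JSON config has sections `detector`, `spectrogram`, `svm`,
`evaluation` and `soundscape`; any omitted key falls back to the published
defaults (1000–6100 Hz band, 0.5–5 s durations, 70/30 × 1000 holdout,
grid 10^-10 … 10^10). `meta.csv` needs columns
`source_id,site,point,minutes`.

Selection tables are tab-delimited in the Raven selection-table dialect
(`Selection / View / Channel / Begin Time (s) / End Time (s) / Low Freq
(Hz) / High Freq (Hz)` plus an optional `Class` column), so they can be
opened over a spectrogram in standard viewers.

## Library layout

| module | role |
| --- | --- |
| `songscan.audio_io` | WAV read/write, spectrograms with explicit frame conventions |
| `songscan.detector` | band-limited energy detector + config tuning |
| `songscan.annotations` | selection model, Raven table I/O, label binarization |
| `songscan.measurements` | per-selection acoustic features |
| `songscan.classifier` | RBF-SVM train/tune/predict, model persistence |
| `songscan.evaluation` | BAC, ROC/AUC, repeated holdout, learning curve, detector scoring |
| `songscan.survey` | scanning, presence/abundance reports, mixed-model site comparison |
| `songscan.synthetic` | ground-truthed soundscape generation |
| `songscan.cli` | `songscan` command-line entry point |

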