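# eegdfc

EEG emotion-recognition feature selection as a tested, reusable library and
CLI. The pipeline decomposes multichannel EEG with a fast empirical-mode
variant (halved extrema, normalized-envelope stop rule), renders analytic
Morlet spectrogram images (224×224×3), extracts 1000-attribute deep-feature
rows per image from pluggable extractors, selects high-quality channels with a
discernibility (rough-set style) entropy, fuses the four per-model tables into
a combined feature vector with redundant-row elimination, and reduces it by
Deep Feature Clustering — per-class k-means vocabularies plus
histogram-of-vocabulary features — before cross-validated SVM/k-NN/RF
classification.

A seeded synthetic-EEG module emulates the statistical structure the pipeline
assumes (class-dependent beta/gamma band power on informative channels), so
everything is exercisable end-to-end without licensed datasets.

## Library overview

| Module | What it does |
| --- | --- |
| `eegdfc.synthetic` | Seeded corpora of `EEGRecord`s with class-dependent rhythm power |
| `eegdfc.decomposition` | `sift` / `find_extrema` / `halve_extrema` / `reconstruct` (EMD) |
| `eegdfc.tfr` | `analytic_wavelet_tfr` (complex Morlet CWT) and `render_image` |
| `eegdfc.features` | `extract_features` → 1000-column `FeatureTable`; `relu` |
| `eegdfc.selection` | `discernibility_entropy`, `channel_entropy`, `select_channels` (threshold 1.145), `concat_models`, `eliminate_redundant` |
| `eegdfc.dfc` | `build_vocabulary` (k centers per class), `sweep_k`, `histogram_features` |
| `eegdfc.evaluate` | `crossval_classify` (svm_cubic / knn_fine / rf), `cost_entropy`, `precision_sensitivity_f1`, `mutual_information`, `paired_ttest`, `class_distance_report` |
| `eegdfc.pipeline` | `run_pipeline` (cached stages), `shape_report`, YAML `PipelineConfig` |
| `eegdfc.io` / `eegdfc.edf` | corpus + feature-table serialization, minimal EDF writer/reader |

## CLI

```bash
eegdfc synth --subjects 5 --trials 9 --channels 8 --classes 3 --seed 1 --out corpus/
eegdfc decompose --in corpus/ --max-imfs 5 --stop 0.2 --out imfs/
eegdfc tfr --in corpus/ --fmin 1 --fmax 45 --scales 64 --out images/
eegdfc extract --model lite --seed 1 --images images/ --out fv1.npz
eegdfc select-channels --in fv1.npz --threshold 1.145 --bins 4 --out channels.csv
eegdfc combine --in fv1.npz --in fv2.npz --in fv3.npz --in fv4.npz --out cfv.npz
eegdfc dfc build --features cfv.npz --k 10 --seed 1 --out vocab.npz
eegdfc dfc histogram --vocab vocab.npz --features cfv.npz --out hist.npz
eegdfc evaluate --features hist.npz --classifier svm --folds 10 --report out.json
eegdfc shape --obs-per-channel 675 --channels 62 --selected 26
```

Or run everything from one config file:

```bash
eegdfc run --config config.yaml
```

```yaml
# config.yaml (all keys optional; unknown keys rejected)
corpus:   {n_subjects: 5, n_trials_per_subject: 9, n_channels: 8, seed: 1}
sift:     {max_imfs: 5, stop_threshold: 0.2, halve_extrema: true}
tfr:      {f_min: 1.0, f_max: 45.0, n_scales: 64}
extract:  {models: [lite], seeds: [1, 2, 3, 4]}   # 4 lite models -> CFV = 4 x FV
selection: {threshold: 1.145, n_attributes: 8}
dfc:      {k_per_class: 10, seed: 0}
evaluate: {classifier: svm_cubic, n_folds: 10, seed: 0}
output_dir: pipeline_out
```

Stages are cached under `output_dir` keyed by config-section hashes; reruns
with an unchanged config skip straight to the report.

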