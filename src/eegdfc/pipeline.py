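"""End-to-end orchestration: config file, stage caching, shape ledger.

``run_pipeline`` executes synth -> decompose -> tfr -> extract (x4 lite
seeds or pretrained models) -> channel selection -> concat + RFE -> DFC
vocabulary/histograms -> cross-validated evaluation, writing per-stage
artifacts and manifests under the configured output directory.  Stages
are skipped on rerun when their artifact exists and the stored config
hash still matches.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .decomposition import SiftConfig, sift
from .dfc import build_vocabulary, histogram_features
from .evaluate import EvaluationReport, crossval_classify
from .exceptions import ConfigurationError, DataError
from .features import ExtractorSpec, FeatureTable, extract_features
from .io import load_feature_table, save_feature_table, write_corpus
from .selection import (
    concat_models,
    eliminate_redundant,
    restrict_to_channels,
    select_channels,
)
from .synthetic import CorpusSpec, generate_corpus
from .tfr import analytic_wavelet_tfr, denoised_signal, render_image

logger = logging.getLogger(__name__)


def shape_report(
    obs_per_channel: int, n_channels: int, n_models: int, n_selected: int
) -> dict[str, int]:
    """Stage-dimension ledger: FV, channel-selected FV and CFV row counts."""
    for name, v in (
        ("obs_per_channel", obs_per_channel),
        ("n_channels", n_channels),
        ("n_models", n_models),
        ("n_selected", n_selected),
    ):
        if int(v) < 1:
            raise ConfigurationError(f"{name} must be a positive integer")
    fv = int(obs_per_channel) * int(n_channels)
    selected = int(obs_per_channel) * int(n_selected)
    return {
        "fv_rows": fv,
        "selected_fv_rows": selected,
        "cfv_rows": int(n_models) * selected,
    }


@dataclass
class PipelineConfig:
    corpus: dict = field(default_factory=dict)
    sift: dict = field(default_factory=dict)
    tfr: dict = field(default_factory=lambda: {"f_min": 1.0, "f_max": 45.0, "n_scales": 64})
    extract: dict = field(default_factory=lambda: {"models": ["lite"], "seeds": [1, 2, 3, 4]})
    selection: dict = field(
        default_factory=lambda: {
            "threshold": 1.145,
            "n_bins": None,  # None -> one bin per class
            "n_attributes": 8,
            "top_m": None,
            "rfe_epsilon": "auto",
        }
    )
    dfc: dict = field(default_factory=lambda: {"k_per_class": 10, "seed": 0})
    evaluate: dict = field(default_factory=lambda: {"classifier": "svm_cubic", "n_folds": 10, "seed": 0})
    output_dir: str = "pipeline_out"
    corpus_format: str = "npy"

    _KNOWN = (
        "corpus", "sift", "tfr", "extract", "selection", "dfc",
        "evaluate", "output_dir", "corpus_format",
    )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - set(cls._KNOWN)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        for key, value in data.items():
            current = getattr(cfg, key)
            if isinstance(current, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def section_hash(self, *sections: str) -> str:
        payload = {s: getattr(self, s) for s in sections}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _cache_valid(artifact: Path, sidecar: Path, config_hash: str) -> bool:
    if not (artifact.exists() and sidecar.exists()):
        return False
    try:
        meta = json.loads(sidecar.read_text())
    except (json.JSONDecodeError, OSError) as exc:
        raise DataError(f"corrupted stage manifest {sidecar}: {exc}") from exc
    return meta.get("config_hash") == config_hash


def _write_sidecar(sidecar: Path, config_hash: str, **extra) -> None:
    sidecar.write_text(json.dumps({"config_hash": config_hash, **extra}, indent=1))


def run_pipeline(config: PipelineConfig) -> tuple[EvaluationReport, dict]:
    """Run every stage; returns the evaluation report and stage artifacts."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}
    timings: dict[str, float] = {}

    # --- corpus -----------------------------------------------------------
    t0 = time.perf_counter()
    spec = CorpusSpec(**{
        k: (tuple(v) if k == "informative_channels" else v)
        for k, v in config.corpus.items()
    })
    records = generate_corpus(spec)
    corpus_hash = config.section_hash("corpus")
    corpus_dir = out / "corpus"
    if not _cache_valid(corpus_dir / "manifest.csv", out / "corpus.json", corpus_hash):
        write_corpus(records, corpus_dir, fmt=config.corpus_format)
        _write_sidecar(out / "corpus.json", corpus_hash, n_records=len(records))
    timings["corpus"] = time.perf_counter() - t0

    # --- decompose + tfr + extract (cached as one feature stage) ----------
    t0 = time.perf_counter()
    feat_hash = config.section_hash("corpus", "sift", "tfr", "extract")
    model_specs = _extractor_specs(config)
    feature_paths = [out / f"features_{s.model_name}.npz" for s in model_specs]
    if all(
        _cache_valid(p, out / f"features_{s.model_name}.json", feat_hash)
        for p, s in zip(feature_paths, model_specs)
    ):
        tables = [load_feature_table(p) for p in feature_paths]
        logger.info("feature stage: cache hit")
    else:
        tables = _compute_features(records, config, model_specs)
        for table, spec_, path in zip(tables, model_specs, feature_paths):
            save_feature_table(table, path)
            _write_sidecar(out / f"features_{spec_.model_name}.json", feat_hash,
                           n_rows=table.n_observations)
    artifacts["feature_tables"] = tables
    timings["features"] = time.perf_counter() - t0

    # --- channel selection ------------------------------------------------
    t0 = time.perf_counter()
    sel = config.selection
    report = select_channels(
        tables[0],
        threshold=sel.get("threshold", 1.145),
        n_bins=sel.get("n_bins") or spec.n_classes,
        n_attributes=sel.get("n_attributes", 8),
    )
    top_m = sel.get("top_m")
    if top_m:
        selected = report.top_channels(int(top_m))
    elif report.empty:
        logger.warning("empty threshold selection; falling back to all channels")
        selected = tables[0].channels()
    else:
        selected = report.selected_channels
    artifacts["channel_report"] = report
    artifacts["selected_channels"] = selected
    (out / "channels.json").write_text(json.dumps({
        "entropy": {str(c): report.per_channel_entropy[c] for c in report.per_channel_entropy},
        "selected": [str(c) for c in selected],
    }, indent=1))
    timings["selection"] = time.perf_counter() - t0

    # --- concat + RFE -----------------------------------------------------
    t0 = time.perf_counter()
    selected_tables = [restrict_to_channels(t, selected) for t in tables]
    if len(selected_tables) == 4:
        cfv = concat_models(selected_tables)
    else:  # single-extractor runs keep the CFV contract with one model
        base = selected_tables[0]
        cfv_rows = np.vstack([t.rows for t in selected_tables])
        cfv_keys = [k for t in selected_tables for k in t.keys]
        from .selection import CombinedFeatureVector

        cfv = CombinedFeatureVector(rows=cfv_rows, keys=cfv_keys, stage="CFV")
    eps = sel.get("rfe_epsilon", "auto")
    cfv_rfe = eliminate_redundant(cfv, None if eps in ("auto", None) else float(eps))
    artifacts["cfv"] = cfv
    artifacts["cfv_rfe"] = cfv_rfe
    timings["fusion"] = time.perf_counter() - t0

    # --- DFC --------------------------------------------------------------
    t0 = time.perf_counter()
    vocab = build_vocabulary(
        cfv_rfe,
        k_per_class=config.dfc.get("k_per_class", 10),
        seed=config.dfc.get("seed", 0),
    )
    hist = histogram_features(vocab, cfv_rfe)
    artifacts["vocabulary"] = vocab
    artifacts["histograms"] = hist
    timings["dfc"] = time.perf_counter() - t0

    # --- evaluation -------------------------------------------------------
    t0 = time.perf_counter()
    ev = config.evaluate
    report_ev = crossval_classify(
        hist,
        classifier=ev.get("classifier", "svm_cubic"),
        n_folds=ev.get("n_folds", 10),
        seed=ev.get("seed", 0),
    )
    timings["evaluate"] = time.perf_counter() - t0
    (out / "report.json").write_text(json.dumps(report_ev.to_dict(), indent=1))
    artifacts["timings"] = timings
    for stage, dt in timings.items():
        logger.info("stage %-10s %.2fs", stage, dt)
    return report_ev, artifacts


def _extractor_specs(config: PipelineConfig) -> list[ExtractorSpec]:
    models = config.extract.get("models", ["lite"])
    seeds = config.extract.get("seeds", [1, 2, 3, 4])
    specs = []
    for m in models:
        if m == "lite":
            specs.extend(ExtractorSpec(name="lite", seed=s) for s in seeds)
        else:
            specs.append(ExtractorSpec(name=m))
    return specs


def process_record(record, sift_config: SiftConfig, tfr_config: dict):
    """Decompose every channel, rebuild the denoised signal and render images."""
    images = []
    for ch in range(record.n_channels):
        imfset = sift(record.samples[ch], sift_config)
        clean = denoised_signal(imfset)
        spec = analytic_wavelet_tfr(
            clean,
            record.sampling_rate,
            n_scales=tfr_config.get("n_scales", 64),
            f_min=tfr_config.get("f_min", 1.0),
            f_max=tfr_config.get("f_max", 45.0),
            provenance=(record.subject_id, record.trial_id, record.channel_labels[ch]),
        )
        images.append(render_image(spec, colormap=tfr_config.get("colormap", "viridis")))
    return images


def _compute_features(records, config: PipelineConfig, model_specs) -> list[FeatureTable]:
    sift_config = SiftConfig(**config.sift)
    images, labels = [], []
    for record in records:
        imgs = process_record(record, sift_config, config.tfr)
        images.extend(imgs)
        labels.extend([record.class_label] * len(imgs))
    return [extract_features(images, spec, class_labels=labels) for spec in model_specs]
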