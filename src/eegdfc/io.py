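"""Corpus and feature-table serialization: array directories, manifests, PNGs."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image

from .edf import read_edf, write_edf
from .exceptions import DataError
from .features import FeatureTable
from .synthetic import EEGRecord
from .tfr import SpectroImage

MANIFEST = "manifest.csv"


def _record_stem(r: EEGRecord) -> str:
    return f"s{r.subject_id:03d}_t{r.trial_id:03d}"


def write_corpus(records: list[EEGRecord], out_dir, fmt: str = "npy") -> Path:
    """Write one file per record plus a CSV manifest.

    ``fmt`` is ``npy`` (float64 channel x sample arrays) or ``edf``.
    """
    if fmt not in ("npy", "edf"):
        raise DataError(f"unknown corpus format {fmt!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        fname = f"{_record_stem(r)}.{fmt}"
        if fmt == "npy":
            np.save(out / fname, r.samples)
        else:
            write_edf(r, out / fname)
        rows.append(
            {
                "subject": r.subject_id,
                "trial": r.trial_id,
                "class": r.class_label,
                "sampling_rate": r.sampling_rate,
                "channels": ";".join(r.channel_labels),
                "file": fname,
            }
        )
    with open(out / MANIFEST, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return out


def read_corpus(in_dir) -> list[EEGRecord]:
    in_dir = Path(in_dir)
    manifest = in_dir / MANIFEST
    if not manifest.exists():
        raise DataError(f"missing corpus manifest {manifest}")
    records = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            path = in_dir / row["file"]
            if path.suffix == ".npy":
                samples = np.load(path)
                fs = float(row["sampling_rate"])
                labels = row["channels"].split(";")
            elif path.suffix == ".edf":
                samples, fs, labels, _ = read_edf(path)
            else:
                raise DataError(f"unknown corpus file type {path.name!r}")
            records.append(
                EEGRecord(
                    subject_id=int(row["subject"]),
                    trial_id=int(row["trial"]),
                    class_label=int(row["class"]),
                    sampling_rate=fs,
                    channel_labels=labels,
                    samples=samples,
                )
            )
    return records


def write_images(images: list[SpectroImage], out_dir) -> Path:
    """PNG per image, named subject_trial_channel.png, plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        subject, trial, channel = img.provenance[:3]
        fname = f"{subject}_{trial}_{channel}.png"
        Image.fromarray(img.pixels, mode="RGB").save(out / fname)
        rows.append({"subject": subject, "trial": trial, "channel": channel, "file": fname})
    with open(out / MANIFEST, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)
    return out


def save_feature_table(table: FeatureTable, path) -> None:
    """Columnar binary (.npz) holding rows + a parallel key manifest."""
    path = Path(path)
    keys = np.array([[str(f) for f in k] for k in table.keys])
    np.savez(path, rows=table.rows, keys=keys)


def load_feature_table(path) -> FeatureTable:
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing feature table {path}")
    data = np.load(path, allow_pickle=False)
    keys = [tuple(k) for k in data["keys"].tolist()]
    return FeatureTable(rows=data["rows"], keys=keys)
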