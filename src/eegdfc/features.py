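"""Deep-feature extraction: 1000-attribute rows per spectrogram image.

Extractors are pluggable.  The ``lite`` extractor — pooled patch statistics
pushed through a seeded fixed random projection and a ReLU — is the default
and needs no downloads; pretrained CNN backbones (resnet50, googlenet,
inception_v4, vgg16) are optional adapters that tap the 1000-way
fully-connected layer and require torch/torchvision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DataError, DependencyError
from .tfr import IMAGE_SIZE, SpectroImage

N_FEATURES = 1000
_PATCH_GRID = 8
_N_PATCH_STATS = _PATCH_GRID * _PATCH_GRID * 2 * 3  # mean+sd per RGB cell


def relu(x):
    """max(0, x), element-wise on arrays."""
    return np.maximum(0, x)


@dataclass
class ExtractorSpec:
    name: str = "lite"
    weights_source: str | None = None
    seed: int = 0
    layer: str | None = None  # FC tap point for pretrained adapters

    _KNOWN = ("lite", "resnet50", "googlenet", "inception_v4", "vgg16")

    def __post_init__(self) -> None:
        if self.name not in self._KNOWN:
            raise DataError(f"unknown extractor {self.name!r}; expected one of {self._KNOWN}")

    @property
    def model_name(self) -> str:
        return f"lite{self.seed}" if self.name == "lite" else self.name


@dataclass
class FeatureTable:
    """n_observations x 1000 feature rows with parallel keys.

    Keys are (subject, trial, channel, model_name, class_label) tuples and
    must be unique.
    """

    rows: np.ndarray
    keys: list[tuple]

    def __post_init__(self) -> None:
        r = np.asarray(self.rows, dtype=float)
        if r.ndim != 2 or r.shape[1] != N_FEATURES:
            raise DataError(f"rows must have exactly {N_FEATURES} columns, got {r.shape}")
        if not np.all(np.isfinite(r)):
            raise DataError("feature rows must be finite")
        if len(self.keys) != r.shape[0]:
            raise DataError("keys must parallel rows")
        if len(set(self.keys)) != len(self.keys):
            raise DataError("feature keys must be unique")
        self.rows = r
        self.keys = [tuple(k) for k in self.keys]

    @property
    def n_observations(self) -> int:
        return self.rows.shape[0]

    def labels(self) -> np.ndarray:
        return np.asarray([k[4] for k in self.keys])

    def channels(self) -> list:
        return sorted({k[2] for k in self.keys})


def _patch_statistics(pixels: np.ndarray) -> np.ndarray:
    """8x8 grid of per-cell mean/SD per RGB channel -> 384 values in [0, 1]."""
    img = pixels.astype(float) / 255.0
    cell = IMAGE_SIZE // _PATCH_GRID
    cells = img.reshape(_PATCH_GRID, cell, _PATCH_GRID, cell, 3)
    means = cells.mean(axis=(1, 3))
    sds = cells.std(axis=(1, 3))
    return np.concatenate([means.ravel(), sds.ravel()])


def _lite_projection(seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([0x11FE, seed]))
    return rng.standard_normal((_N_PATCH_STATS, N_FEATURES)) / np.sqrt(_N_PATCH_STATS)


def _extract_lite(images: list[SpectroImage], seed: int) -> np.ndarray:
    proj = _lite_projection(seed)
    stats = np.stack([_patch_statistics(img.pixels) for img in images])
    return relu(stats @ proj)


def _extract_pretrained(images: list[SpectroImage], spec: ExtractorSpec) -> np.ndarray:
    try:
        import torch
        import torchvision.models as tvm
    except ImportError as exc:  # pragma: no cover - optional extra
        raise DependencyError(
            f"extractor {spec.name!r} needs torch/torchvision; install the "
            "'pretrained' extra or use the 'lite' extractor"
        ) from exc
    factories = {
        "resnet50": tvm.resnet50,
        "googlenet": tvm.googlenet,
        "vgg16": tvm.vgg16,
        "inception_v4": getattr(tvm, "inception_v3", None),  # closest stock analogue
    }
    factory = factories[spec.name]
    if factory is None:  # pragma: no cover
        raise DependencyError(f"no torchvision factory for {spec.name!r}")
    model = factory(weights="DEFAULT" if spec.weights_source is None else None)
    if spec.weights_source is not None:
        model.load_state_dict(torch.load(spec.weights_source, map_location="cpu"))
    model.eval()
    mean = torch.tensor([0.485, 0.456, 0.406]).view(3, 1, 1)
    std = torch.tensor([0.229, 0.224, 0.225]).view(3, 1, 1)
    batch = torch.stack(
        [
            (torch.from_numpy(img.pixels.copy()).permute(2, 0, 1).float() / 255.0 - mean)
            / std
            for img in images
        ]
    )
    with torch.no_grad():
        out = model(batch)  # final 1000-way FC, classification layers unused
    return out.numpy().astype(float)


def extract_features(
    images: list[SpectroImage],
    extractor: ExtractorSpec | None = None,
    class_labels: list | None = None,
) -> FeatureTable:
    """One 1000-dim feature row per image; deterministic per (extractor, image).

    ``class_labels`` parallels ``images``; when omitted, labels default to
    None in the keys.
    """
    extractor = extractor or ExtractorSpec()
    if class_labels is None:
        class_labels = [None] * len(images)
    if len(class_labels) != len(images):
        raise DataError("class_labels must parallel images")
    for img in images:
        if img.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise DataError("images must be 224x224x3")
    if extractor.name == "lite":
        rows = _extract_lite(images, extractor.seed)
    else:
        rows = _extract_pretrained(images, extractor)
    keys = []
    for i, (img, label) in enumerate(zip(images, class_labels)):
        prov = tuple(img.provenance)[:3]
        prov = prov + tuple(f"img{i}" for _ in range(3 - len(prov)))
        keys.append((*prov, extractor.model_name, label))
    return FeatureTable(rows=rows, keys=keys)
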