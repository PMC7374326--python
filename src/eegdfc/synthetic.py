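"""Seeded synthetic multichannel EEG corpora.

Generates trials whose informative channels carry class-dependent rhythm
(band) power on top of Gaussian noise, so that every downstream stage of
the pipeline — decomposition, time-frequency imaging, feature extraction,
channel selection and clustering — can be exercised without licensed data.

The signal model is a sum of band-limited sinusoids with random phases
plus white noise.  Only the spectral content differs between classes;
no attempt is made at physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

#: Conventional EEG rhythm band edges in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: 10-20 system electrode names used for default channel labels.
TEN_TWENTY_LABELS = [
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz", "Oz",
    "A1", "A2", "Pg1", "Pg2",
]


def default_class_band_powers(n_classes: int) -> dict[int, dict[str, float]]:
    """Per-class relative band powers; each class dominates a distinct rhythm.

    High-frequency rhythms are assigned first (beta/gamma carry the most
    emotion-discriminative content), then alpha/theta for 4-class corpora.
    """
    dominant = ["gamma", "beta", "alpha", "theta"]
    powers = {}
    for c in range(n_classes):
        row = {band: 0.05 for band in BANDS}
        row[dominant[c % len(dominant)]] = 4.0
        powers[c] = row
    return powers


@dataclass(frozen=True)
class EEGRecord:
    """One trial's multichannel signal plus metadata."""

    subject_id: int
    trial_id: int
    class_label: int
    sampling_rate: float
    channel_labels: list[str]
    samples: np.ndarray  # (n_channels, n_samples)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[0] < 1 or s.shape[1] < 2:
            raise ConfigurationError("samples must be (n_channels >= 1, n_samples >= 2)")
        if not np.all(np.isfinite(s)):
            raise ConfigurationError("samples must be finite")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        object.__setattr__(self, "samples", s)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class CorpusSpec:
    """Shape and statistical structure of a synthetic corpus.

    Defaults mirror a miniature 3-class corpus: 5 subjects x 9 trials x
    8 channels at 200 Hz, 4-second trials.
    """

    n_subjects: int = 5
    n_trials_per_subject: int = 9
    n_channels: int = 8
    n_classes: int = 3
    sampling_rate: float = 200.0
    trial_duration: float = 4.0
    class_band_powers: dict[int, dict[str, float]] | None = None
    informative_channels: tuple[int, ...] = (0, 1)
    noise_sd: float = 0.5
    seed: int = 0
    n_tones_per_band: int = 3

    def validate(self) -> None:
        for name in ("n_subjects", "n_trials_per_subject", "n_channels"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.n_classes not in (3, 4):
            raise ConfigurationError("n_classes must be 3 or 4")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.trial_duration <= 0:
            raise ConfigurationError("trial_duration must be > 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        bad = [c for c in self.informative_channels if not 0 <= c < self.n_channels]
        if bad:
            raise ConfigurationError(
                f"informative_channels contains out-of-range indices {bad}"
            )
        for c, row in (self.class_band_powers or {}).items():
            if not 0 <= c < self.n_classes:
                raise ConfigurationError(f"class_band_powers has unknown class {c}")
            unknown = set(row) - set(BANDS)
            if unknown:
                raise ConfigurationError(f"class_band_powers names unknown bands {unknown}")
            if any(v < 0 for v in row.values()):
                raise ConfigurationError("class_band_powers values must be non-negative")

    def resolved_band_powers(self) -> dict[int, dict[str, float]]:
        if self.class_band_powers is not None:
            return self.class_band_powers
        return default_class_band_powers(self.n_classes)

    def channel_labels(self) -> list[str]:
        labels = list(TEN_TWENTY_LABELS[: self.n_channels])
        labels += [f"Ch{i}" for i in range(len(labels), self.n_channels)]
        return labels


def _record_rng(seed: int, subject: int, trial: int) -> np.random.Generator:
    # SeedSequence keyed on (corpus seed, subject, trial): any subset of
    # records is reproducible without generating the rest of the corpus.
    return np.random.default_rng(np.random.SeedSequence([seed, subject, trial]))


def _class_tone_frequencies(
    seed: int, label: int, band_index: int, band: tuple[float, float],
    n_tones: int, nyquist: float,
) -> np.ndarray:
    """Tone frequencies are fixed per (corpus, class, band): the class's
    spectral signature is stable across trials, only phases vary."""
    lo, hi = band
    hi = min(hi, 0.95 * nyquist)
    if hi <= lo:
        return np.empty(0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919, label, band_index]))
    return rng.uniform(lo, hi, size=n_tones)


def _band_signal(
    rng: np.random.Generator,
    t: np.ndarray,
    freqs: np.ndarray,
    power: float,
) -> np.ndarray:
    if freqs.size == 0 or power <= 0:
        return np.zeros_like(t)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    # each tone of amplitude A contributes A^2/2 power; split `power` evenly
    amp = np.sqrt(2.0 * power / freqs.size)
    return amp * np.sin(2.0 * np.pi * freqs[:, None] * t + phases[:, None]).sum(axis=0)


def generate_record(spec: CorpusSpec, subject: int, trial: int, label: int) -> EEGRecord:
    """Generate one trial; deterministic in (spec.seed, subject, trial)."""
    rng = _record_rng(spec.seed, subject, trial)
    n = int(round(spec.sampling_rate * spec.trial_duration))
    t = np.arange(n) / spec.sampling_rate
    powers = spec.resolved_band_powers()[label]
    informative = set(spec.informative_channels)
    samples = np.empty((spec.n_channels, n))
    for ch in range(spec.n_channels):
        x = rng.normal(0.0, spec.noise_sd, size=n)
        if ch in informative:
            for bi, (band_name, power) in enumerate(sorted(powers.items())):
                freqs = _class_tone_frequencies(
                    spec.seed, label, bi, BANDS[band_name],
                    spec.n_tones_per_band, spec.sampling_rate / 2.0,
                )
                x += _band_signal(rng, t, freqs, power)
        samples[ch] = x
    return EEGRecord(
        subject_id=subject,
        trial_id=trial,
        class_label=label,
        sampling_rate=spec.sampling_rate,
        channel_labels=spec.channel_labels(),
        samples=samples,
    )


def generate_corpus(spec: CorpusSpec) -> list[EEGRecord]:
    """Generate the full corpus: n_subjects x n_trials_per_subject records.

    Class labels are assigned round-robin over the flattened (subject,
    trial) order so counts are balanced to within one.  Identical specs
    (including seed) produce bit-identical corpora.
    """
    spec.validate()
    records = []
    idx = 0
    for subject in range(spec.n_subjects):
        for trial in range(spec.n_trials_per_subject):
            label = idx % spec.n_classes
            records.append(generate_record(spec, subject, trial, label))
            idx += 1
    return records
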