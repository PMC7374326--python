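"""Channel selection and feature-vector fusion.

Channels are scored with a discernibility (rough-set style) entropy: the
full feature table and the candidate channel's features each induce a
partition of the observations via per-attribute equal-frequency binning,
and the entropy measures how much coarser the channel's partition is than
the full one.  Channels whose features carry a shared class-driven signal
produce coarse, structured partitions and score high; independent-noise
channels shatter into singletons and score near zero.

Also here: concatenation of the four per-model feature tables into the
combined feature vector (CFV) and greedy Euclidean-distance elimination
of redundant rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DataError
from .features import N_FEATURES, FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 1.145
DEFAULT_N_BINS = 4
DEFAULT_N_ATTRIBUTES = 8
N_MODELS = 4

STAGES = ("FV", "FV_selected", "CFV", "CFV_rfe")


@dataclass
class ChannelEntropyReport:
    per_channel_entropy: dict
    threshold: float
    selected_channels: list

    def __post_init__(self) -> None:
        for c, e in self.per_channel_entropy.items():
            if not np.isfinite(e) or e < 0:
                raise DataError(f"entropy for channel {c!r} must be finite and >= 0")
        expected = [
            c for c, e in self.per_channel_entropy.items() if e > self.threshold
        ]
        if sorted(map(str, expected)) != sorted(map(str, self.selected_channels)):
            raise DataError("selected_channels must be the strict superlevel set")

    @property
    def empty(self) -> bool:
        return not self.selected_channels

    def top_channels(self, m: int) -> list:
        ranked = sorted(
            self.per_channel_entropy, key=lambda c: (-self.per_channel_entropy[c], str(c))
        )
        return ranked[:m]


@dataclass
class CombinedFeatureVector:
    rows: np.ndarray
    keys: list[tuple]
    stage: str = "CFV"

    def __post_init__(self) -> None:
        r = np.asarray(self.rows, dtype=float)
        if r.ndim != 2 or r.shape[1] != N_FEATURES:
            raise DataError(f"rows must have {N_FEATURES} columns")
        if self.stage not in STAGES:
            raise DataError(f"unknown stage {self.stage!r}")
        if len(self.keys) != r.shape[0]:
            raise DataError("keys must parallel rows")
        self.rows = r
        self.keys = [tuple(k) for k in self.keys]

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    def labels(self) -> np.ndarray:
        return np.asarray([k[4] for k in self.keys])


# ---------------------------------------------------------------------------
# discernibility entropy over partitions


def _check_partition(blocks, universe: set, name: str) -> None:
    seen: set = set()
    for b in blocks:
        if not b:
            raise DataError(f"{name} contains an empty block")
        if seen & set(b):
            raise DataError(f"{name} blocks overlap")
        seen |= set(b)
    if seen != universe:
        raise DataError(f"{name} does not cover the universe")


def discernibility_entropy(partition_c, partition_p) -> float:
    """E = -(1/|U|) * sum_x log2(|x_C| / |x_P|).

    ``partition_c`` must refine ``partition_p`` (each C-block lies inside
    one P-block).  E is zero iff the partitions coincide, and shrinks as
    the coarse partition P is refined toward C.
    """
    blocks_c = [frozenset(b) for b in partition_c]
    blocks_p = [frozenset(b) for b in partition_p]
    universe = set().union(*blocks_c) if blocks_c else set()
    universe_p = set().union(*blocks_p) if blocks_p else set()
    if universe != universe_p or not universe:
        raise DataError("partitions must cover the same non-empty universe")
    _check_partition(blocks_c, universe, "partition_c")
    _check_partition(blocks_p, universe, "partition_p")
    p_of: dict = {}
    for b in blocks_p:
        for x in b:
            p_of[x] = b
    total = 0.0
    for bc in blocks_c:
        bp = p_of[next(iter(bc))]
        if not bc <= bp:
            raise DataError("partition_c must refine partition_p")
        total += len(bc) * np.log2(len(bc) / len(bp))
    return float(-total / len(universe))


# ---------------------------------------------------------------------------
# partitions from binned feature tables


def _equal_frequency_bins(column: np.ndarray, n_bins: int) -> np.ndarray:
    # quantile-edge digitization: tied values always share a bin (a rank
    # split would scatter constant columns across bins)
    edges = np.quantile(column, np.linspace(0.0, 1.0, n_bins + 1)[1:-1])
    return np.searchsorted(edges, column, side="right")


def _bin_matrix(rows: np.ndarray, n_bins: int, n_attributes: int | None) -> np.ndarray:
    cols = rows if n_attributes is None else rows[:, :n_attributes]
    return np.stack(
        [_equal_frequency_bins(cols[:, j], n_bins) for j in range(cols.shape[1])],
        axis=1,
    )


def _partition_from_codes(codes: np.ndarray) -> list[list[int]]:
    _, inverse = np.unique(codes, axis=0, return_inverse=True)
    blocks: dict[int, list[int]] = {}
    for obj, g in enumerate(inverse):
        blocks.setdefault(int(g), []).append(obj)
    return list(blocks.values())


def _observation_layout(features: FeatureTable, n_bins: int):
    """Bin all features and lay them out as objects x (channel-attribute blocks).

    Objects are (subject, trial, model) observations; each channel
    contributes one block of binned attribute columns per object.  The
    full layout induces the "full set" partition C; slicing a channel's
    block (optionally limited to the first ``n_attributes`` columns)
    induces the channel's partition P, which C refines by construction.
    """
    channels = features.channels()
    obj_keys = sorted({(k[0], k[1], k[3]) for k in features.keys})
    obj_index = {k: i for i, k in enumerate(obj_keys)}
    # bin each attribute over all rows (channels pooled), per the
    # equal-frequency-per-attribute discretization of the feature table
    binned = _bin_matrix(features.rows, n_bins, None)
    n_attr = binned.shape[1]
    layout = np.full((len(obj_keys), len(channels) * n_attr), -1, dtype=np.int32)
    ch_index = {c: j for j, c in enumerate(channels)}
    for row_i, key in enumerate(features.keys):
        obj = obj_index[(key[0], key[1], key[3])]
        j = ch_index[key[2]]
        layout[obj, j * n_attr : (j + 1) * n_attr] = binned[row_i]
    if np.any(layout < 0):
        raise DataError("feature table is not complete over (subject, trial, model) x channel")
    return layout, channels, n_attr


def _channel_slice(layout, j: int, n_attr: int, n_attributes: int | None):
    block = layout[:, j * n_attr : (j + 1) * n_attr]
    return block if n_attributes is None else block[:, :n_attributes]


def channel_entropy(
    features: FeatureTable,
    channel,
    n_bins: int = DEFAULT_N_BINS,
    n_attributes: int | None = DEFAULT_N_ATTRIBUTES,
) -> float:
    """Discernibility entropy of one channel against the full feature set."""
    layout, channels, n_attr = _observation_layout(features, n_bins)
    if channel not in channels:
        raise KeyError(f"channel {channel!r} not present in feature table")
    j = channels.index(channel)
    part_c = _partition_from_codes(layout)
    part_p = _partition_from_codes(_channel_slice(layout, j, n_attr, n_attributes))
    return discernibility_entropy(part_c, part_p)


def select_channels(
    features: FeatureTable,
    threshold: float = DEFAULT_THRESHOLD,
    n_bins: int = DEFAULT_N_BINS,
    n_attributes: int | None = DEFAULT_N_ATTRIBUTES,
) -> ChannelEntropyReport:
    """Score every channel and keep those with entropy strictly above threshold."""
    layout, channels, n_attr = _observation_layout(features, n_bins)
    part_c = _partition_from_codes(layout)
    entropies = {}
    for j, c in enumerate(channels):
        part_p = _partition_from_codes(_channel_slice(layout, j, n_attr, n_attributes))
        entropies[c] = discernibility_entropy(part_c, part_p)
    selected = [c for c in channels if entropies[c] > threshold]
    report = ChannelEntropyReport(
        per_channel_entropy=entropies, threshold=threshold, selected_channels=selected
    )
    if report.empty:
        logger.warning("channel selection at threshold %.4g is empty", threshold)
    return report


def restrict_to_channels(features: FeatureTable, channels) -> FeatureTable:
    wanted = set(channels)
    mask = [k[2] in wanted for k in features.keys]
    if not any(mask):
        raise DataError(f"no rows for channels {sorted(map(str, wanted))}")
    idx = np.flatnonzero(mask)
    return FeatureTable(
        rows=features.rows[idx], keys=[features.keys[i] for i in idx]
    )


# ---------------------------------------------------------------------------
# fusion


def concat_models(tables: list[FeatureTable]) -> CombinedFeatureVector:
    """Row-stack the four per-model feature tables into the CFV."""
    if len(tables) != N_MODELS:
        raise DataError(f"concat_models expects exactly {N_MODELS} tables, got {len(tables)}")
    base = {(k[0], k[1], k[2]) for k in tables[0].keys}
    for i, t in enumerate(tables[1:], start=2):
        other = {(k[0], k[1], k[2]) for k in t.keys}
        if other != base:
            missing = sorted(map(str, base ^ other))
            raise DataError(f"table {i} key mismatch: {missing[:10]}")
    rows = np.vstack([t.rows for t in tables])
    keys = [k for t in tables for k in t.keys]
    return CombinedFeatureVector(rows=rows, keys=keys, stage="CFV")


def auto_epsilon(rows: np.ndarray) -> float:
    norms = np.linalg.norm(rows, axis=1)
    return 1e-6 * float(np.median(norms))


def eliminate_redundant(
    cfv: CombinedFeatureVector, epsilon: float | None = None
) -> CombinedFeatureVector:
    """Greedy scan in key order, dropping rows within ``epsilon`` of a kept row.

    ``epsilon=None`` means 1e-6 x the median row norm.  Idempotent, and the
    retained rows are pairwise >= epsilon apart.
    """
    if epsilon is None:
        epsilon = auto_epsilon(cfv.rows)
    if epsilon < 0:
        raise DataError("epsilon must be >= 0")
    order = sorted(range(cfv.n_rows), key=lambda i: (cfv.keys[i], i))
    kept: list[int] = []
    kept_rows = np.empty((cfv.n_rows, cfv.rows.shape[1]))
    n_kept = 0
    for i in order:
        row = cfv.rows[i]
        if n_kept and epsilon > 0:
            d2 = np.sum((kept_rows[:n_kept] - row) ** 2, axis=1)
            if np.any(d2 < epsilon * epsilon):
                continue
        kept.append(i)
        kept_rows[n_kept] = row
        n_kept += 1
    kept.sort()
    return CombinedFeatureVector(
        rows=cfv.rows[kept], keys=[cfv.keys[i] for i in kept], stage="CFV_rfe"
    )
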