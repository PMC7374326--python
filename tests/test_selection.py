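import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegdfc.exceptions import DataError
from eegdfc.features import FeatureTable
from eegdfc.selection import (
    ChannelEntropyReport,
    CombinedFeatureVector,
    channel_entropy,
    concat_models,
    discernibility_entropy,
    eliminate_redundant,
    restrict_to_channels,
    select_channels,
)

# ---------------------------------------------------------------------------
# independent oracle: direct per-object evaluation of the entropy sum


def brute_force_entropy(partition_c, partition_p):
    universe = sorted(set().union(*map(set, partition_c)))
    total = 0.0
    for x in universe:
        bc = next(b for b in partition_c if x in b)
        bp = next(b for b in partition_p if x in b)
        total += math.log2(len(bc) / len(bp))
    return -total / len(universe)


def random_partition(rng, universe):
    n_blocks = rng.integers(1, len(universe) + 1)
    assignment = rng.integers(0, n_blocks, size=len(universe))
    blocks = {}
    for x, g in zip(universe, assignment):
        blocks.setdefault(g, []).append(x)
    return list(blocks.values())


def refine(rng, partition):
    """Split each block randomly into one or two parts."""
    out = []
    for block in partition:
        if len(block) > 1 and rng.random() < 0.7:
            cut = rng.integers(1, len(block))
            out.extend([block[:cut], block[cut:]])
        else:
            out.append(list(block))
    return out


class TestDiscernibilityEntropy:
    def test_identical_partitions_zero(self):
        p = [[1, 2], [3, 4]]
        assert discernibility_entropy(p, p) == 0.0

    def test_two_blocks_vs_whole(self):
        # -(1/4) * 4 * log2(2/4) = 1.0
        assert discernibility_entropy([[1, 2], [3, 4]], [[1, 2, 3, 4]]) == pytest.approx(1.0)

    def test_singletons_vs_whole(self):
        # -(1/4) * 4 * log2(1/4) = 2.0
        c = [[1], [2], [3], [4]]
        assert discernibility_entropy(c, [[1, 2, 3, 4]]) == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            universe = list(range(int(rng.integers(2, 20))))
            coarse = random_partition(rng, universe)
            fine = refine(rng, coarse)
            assert discernibility_entropy(fine, coarse) == pytest.approx(
                brute_force_entropy(fine, coarse)
            )

    def test_monotonicity_under_refinement(self):
        """Eq-5-style: refining the coarse side increases E; equality iff equal."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            universe = list(range(int(rng.integers(3, 16))))
            p = random_partition(rng, universe)
            b = refine(rng, p)
            c = refine(rng, b)
            # with C fixed finest: E(B) <= E(P)
            assert discernibility_entropy(c, b) <= discernibility_entropy(c, p) + 1e-12
            assert discernibility_entropy(c, c) == 0.0

    def test_refinement_violation_rejected(self):
        with pytest.raises(DataError):
            discernibility_entropy([[1, 2], [3, 4]], [[1, 3], [2, 4]])

    def test_non_partition_rejected(self):
        with pytest.raises(DataError):
            discernibility_entropy([[1, 2], [2, 3]], [[1, 2, 3]])
        with pytest.raises(DataError):
            discernibility_entropy([[1, 2]], [[1, 2, 3]])


# ---------------------------------------------------------------------------
# channel entropy on hand-built tables


def table_from_channel_values(values_by_channel, labels=None):
    """Build a FeatureTable whose first attribute carries the given values
    and the rest are zeros (ties -> single bin, no extra structure)."""
    channels = sorted(values_by_channel)
    n_obs = len(values_by_channel[channels[0]])
    rows, keys = [], []
    for trial in range(n_obs):
        for ch in channels:
            row = np.zeros(1000)
            row[0] = values_by_channel[ch][trial]
            rows.append(row)
            keys.append((0, trial, ch, "m0", labels[trial] if labels else 0))
    return FeatureTable(rows=np.asarray(rows), keys=keys)


class TestChannelEntropy:
    def test_hand_built_matches_oracle(self):
        # 8 observations, 2 channels, 2 bins on attribute 0.
        # channel a: [0,0,0,0,1,1,1,1] -> blocks {0..3}, {4..7}
        # channel b: [0,1,0,1,0,1,0,1] -> blocks {0,2,4,6}, {1,3,5,7}
        # joint C  : pairs {0,2},{1,3},{4,6},{5,7}
        table = table_from_channel_values(
            {"a": [0, 0, 0, 0, 1, 1, 1, 1], "b": [0, 1, 0, 1, 0, 1, 0, 1]}
        )
        joint = [[0, 2], [1, 3], [4, 6], [5, 7]]
        e_a = channel_entropy(table, "a", n_bins=2, n_attributes=1)
        assert e_a == pytest.approx(
            brute_force_entropy(joint, [[0, 1, 2, 3], [4, 5, 6, 7]])
        )
        assert e_a == pytest.approx(1.0)  # -(1/8) * 8 * log2(2/4)
        e_b = channel_entropy(table, "b", n_bins=2, n_attributes=1)
        assert e_b == pytest.approx(
            brute_force_entropy(joint, [[0, 2, 4, 6], [1, 3, 5, 7]])
        )

    def test_channel_matching_full_partition_scores_zero(self):
        # both channels identical -> channel partition equals full partition
        vals = [0, 0, 1, 1]
        table = table_from_channel_values({"a": vals, "b": vals})
        assert channel_entropy(table, "a", n_bins=2, n_attributes=1) == pytest.approx(0.0)

    def test_missing_channel_key_error(self):
        table = table_from_channel_values({"a": [0, 1, 2, 3]})
        with pytest.raises(KeyError):
            channel_entropy(table, "nope")

    def test_adding_attributes_never_increases_entropy(self, small_table):
        channels = small_table.channels()
        for ch in channels[:2]:
            es = [
                channel_entropy(small_table, ch, n_bins=3, n_attributes=m)
                for m in (2, 4, 8, 16)
            ]
            assert all(a >= b - 1e-12 for a, b in zip(es, es[1:]))


class TestSelectChannels:
    def test_identical_channels_all_or_none(self):
        vals = [0, 1, 2, 3, 4, 5]
        table = table_from_channel_values({"a": vals, "b": vals, "c": vals})
        report = select_channels(table, threshold=0.5, n_bins=2, n_attributes=1)
        es = list(report.per_channel_entropy.values())
        assert len(set(np.round(es, 12))) == 1
        assert len(report.selected_channels) in (0, 3)

    def test_infinite_threshold_empty(self):
        table = table_from_channel_values({"a": [0, 1, 2, 3], "b": [3, 2, 1, 0]})
        report = select_channels(table, threshold=float("inf"))
        assert report.selected_channels == [] and report.empty

    def test_strict_threshold(self):
        table = table_from_channel_values(
            {"a": [0, 0, 0, 0, 1, 1, 1, 1], "b": [0, 1, 2, 3, 4, 5, 6, 7]}
        )
        e_a = channel_entropy(table, "a", n_bins=2, n_attributes=1)
        report = select_channels(table, threshold=e_a, n_bins=2, n_attributes=1)
        assert "a" not in report.selected_channels  # ties excluded

    def test_informative_channels_rank_top(self, small_table):
        report = select_channels(small_table, n_bins=3, n_attributes=8)
        assert set(map(str, report.top_channels(2))) == {"Fp1", "Fp2"}

    def test_superlevel_invariant_enforced(self):
        with pytest.raises(DataError):
            ChannelEntropyReport(
                per_channel_entropy={"a": 2.0, "b": 0.5},
                threshold=1.0,
                selected_channels=["b"],
            )


class TestConcatModels:
    def _tables(self, n_models=4, n_rows=6):
        rng = np.random.default_rng(0)
        tables = []
        for m in range(n_models):
            keys = [(0, t, "c0", f"model{m}", t % 2) for t in range(n_rows)]
            tables.append(FeatureTable(rows=rng.normal(size=(n_rows, 1000)), keys=keys))
        return tables

    def test_four_six_row_tables(self):
        cfv = concat_models(self._tables())
        assert cfv.n_rows == 24
        assert cfv.stage == "CFV"
        assert len({k[3] for k in cfv.keys}) == 4

    def test_three_tables_rejected(self):
        with pytest.raises(DataError):
            concat_models(self._tables(n_models=3))

    def test_key_mismatch_rejected(self):
        tables = self._tables()
        bad_keys = [(0, t, "OTHER", "model3", t % 2) for t in range(6)]
        tables[3] = FeatureTable(rows=tables[3].rows, keys=bad_keys)
        with pytest.raises(DataError, match="mismatch"):
            concat_models(tables)


class TestEliminateRedundant:
    def _cfv(self, rows):
        keys = [(0, i, "c0", "m0", 0) for i in range(len(rows))]
        return CombinedFeatureVector(rows=np.asarray(rows), keys=keys)

    def test_duplicates_deduplicated(self):
        base = np.random.default_rng(1).normal(size=(3, 1000))
        cfv = self._cfv(np.vstack([base, base]))
        out = eliminate_redundant(cfv, epsilon=1e-6)
        assert out.n_rows == 3
        assert out.stage == "CFV_rfe"

    def test_epsilon_zero_identity(self):
        cfv = self._cfv(np.random.default_rng(2).normal(size=(5, 1000)))
        out = eliminate_redundant(cfv, epsilon=0.0)
        assert out.n_rows == 5
        assert np.array_equal(out.rows, cfv.rows)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(10, 1000))
        rows = np.vstack([base, base[:5]])
        eps = 1e-3
        cfv = self._cfv(rows)
        out = eliminate_redundant(cfv, epsilon=eps)
        # O(n^2) oracle: same greedy scan, all-pairs distances precomputed
        order = sorted(range(len(rows)), key=lambda i: (cfv.keys[i], i))
        d = np.linalg.norm(rows[:, None, :] - rows[None, :, :], axis=2)
        kept = []
        for i in order:
            if all(d[i, j] >= eps for j in kept):
                kept.append(i)
        assert out.n_rows == len(kept) == 10

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        rows = np.repeat(rng.normal(size=(4, 1000)), 3, axis=0)
        cfv = self._cfv(rows)
        once = eliminate_redundant(cfv, epsilon=1e-4)
        twice = eliminate_redundant(once, epsilon=1e-4)
        assert np.array_equal(once.rows, twice.rows)

    def test_pairwise_distances_at_least_epsilon(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(size=(20, 1000)) * 0.01
        eps = 0.5
        out = eliminate_redundant(self._cfv(rows), epsilon=eps)
        d = np.linalg.norm(out.rows[:, None, :] - out.rows[None, :, :], axis=2)
        iu = np.triu_indices(out.n_rows, k=1)
        assert np.all(d[iu] >= eps)

    def test_negative_epsilon_rejected(self):
        with pytest.raises(DataError):
            eliminate_redundant(self._cfv(np.zeros((2, 1000))), epsilon=-1.0)


def test_restrict_to_channels(small_table):
    out = restrict_to_channels(small_table, ["Fp1"])
    assert all(k[2] == "Fp1" for k in out.keys)
    with pytest.raises(DataError):
        restrict_to_channels(small_table, ["nope"])


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 10_000))
def test_entropy_property_random_chains(seed):
    rng = np.random.default_rng(seed)
    universe = list(range(int(rng.integers(3, 12))))
    p = random_partition(rng, universe)
    b = refine(rng, p)
    assert discernibility_entropy(b, p) >= 0.0
    assert discernibility_entropy(b, p) == pytest.approx(brute_force_entropy(b, p))
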