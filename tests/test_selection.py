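"""Pearson correlation, rank matrix, per-hemisphere channel selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from corrbci.selection import (HemisphereGroup, association_strength,
                               correlation_matrix, pearson_correlation,
                               rank_channels, select_channels)


def pearson_bruteforce(x, y):
    """Element-by-element evaluation of the defining formula (oracle)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = (sum((a - mx) ** 2 for a in x) / n) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / n) ** 0.5
    return cov / (sx * sy)


class TestPearson:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3], [2, 4, 6], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),
    ])
    def test_hand_computed_values(self, x, y, expected):
        assert pearson_correlation(np.array(x, float), np.array(y, float)) \
            == pytest.approx(expected, abs=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert pearson_correlation(x, y) == pytest.approx(
                pearson_bruteforce(list(x), list(y)), abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=st.floats(-5, 5).filter(lambda v: abs(v) > 1e-3),
           b=st.floats(-10, 10), seed=st.integers(0, 100))
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        rho = pearson_correlation(x, y)
        assert pearson_correlation(a * x + b, y) == pytest.approx(
            np.sign(a) * rho, abs=1e-9)

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            pearson_correlation(np.ones(3), np.ones(4))
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation(np.ones(5), np.arange(5.0))


class TestCorrelationMatrix:
    def test_planted_pair_dominates(self, rng):
        base = rng.normal(size=200)
        x = np.vstack([base + 0.05 * rng.normal(size=200),
                       base + 0.05 * rng.normal(size=200),
                       rng.normal(size=200)])
        c = correlation_matrix(x)
        assert c[0, 1] > c[0, 2] and c[0, 1] > c[1, 2]

    def test_symmetric_unit_diagonal(self, rng):
        c = correlation_matrix(rng.normal(size=(5, 80)))
        np.testing.assert_array_equal(c, c.T)
        np.testing.assert_allclose(np.diag(c), 1.0)
        assert np.all(np.abs(c) <= 1.0)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            correlation_matrix(np.ones((1, 10)))

    def test_constant_channel_named(self):
        x = np.vstack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="ch2"):
            correlation_matrix(x, ["ch1", "ch2"])


class TestRankChannels:
    def test_all_ties_keep_input_order(self):
        ids = ["a", "b", "c"]
        ranking = rank_channels(np.ones((3, 3)), ids)
        assert ranking.order == ids
        np.testing.assert_allclose(ranking.scores, 1.0)

    def test_two_channels_share_score(self, rng):
        x = rng.normal(size=(2, 60))
        c = correlation_matrix(x)
        ranking = rank_channels(c, ["p", "q"])
        assert ranking.scores[0] == pytest.approx(abs(c[0, 1]))
        assert ranking.scores[0] == ranking.scores[1]

    def test_permutation_equivariance(self, rng):
        x = rng.normal(size=(5, 120))
        ids = ["c0", "c1", "c2", "c3", "c4"]
        order1 = rank_channels(correlation_matrix(x, ids), ids).order
        perm = [3, 0, 4, 1, 2]
        ids_p = [ids[i] for i in perm]
        order2 = rank_channels(correlation_matrix(x[perm], ids_p), ids_p).order
        assert order1 == order2

    def test_signed_vs_abs_scoring(self):
        c = np.array([[1.0, -0.9, 0.0],
                      [-0.9, 1.0, 0.0],
                      [0.0, 0.0, 1.0]])
        ids = ["a", "b", "c"]
        assert rank_channels(c, ids, score="abs").order[0] == "a"
        assert rank_channels(c, ids, score="signed").order[0] == "c"

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            rank_channels(np.array([[1.0, 0.5], [0.2, 1.0]]), ["a", "b"])
        with pytest.raises(ValueError):
            rank_channels(np.array([[1.0, 1.5], [1.5, 1.0]]), ["a", "b"])


class TestSelectChannels:
    def test_paper_totals(self, preprocessed_session):
        eeg_p, fnirs_p, events, _ = preprocessed_session
        assert len(select_channels(eeg_p, 3, 3, events)) == 6     # 6 of 21
        assert len(select_channels(fnirs_p, 5, 5, events)) == 10  # 10 of 34

    def test_full_k_is_identity(self, preprocessed_session):
        eeg_p, _, events, _ = preprocessed_session
        n_left = len(eeg_p.hemisphere_channels("left"))
        n_right = len(eeg_p.hemisphere_channels("right"))
        sel = select_channels(eeg_p, n_left, n_right, events)
        assert sorted(sel) == sorted(eeg_p.channel_names)

    def test_k_out_of_range(self, preprocessed_session):
        eeg_p, _, events, _ = preprocessed_session
        with pytest.raises(ValueError):
            select_channels(eeg_p, 0, 3, events)
        with pytest.raises(ValueError):
            select_channels(eeg_p, 99, 3, events)

    def test_recovers_planted_at_high_snr(self, preprocessed_session):
        eeg_p, fnirs_p, events, truth = preprocessed_session
        assert sorted(select_channels(eeg_p, 3, 3, events)) \
            == sorted(truth.planted_eeg)
        assert sorted(select_channels(fnirs_p, 5, 5, events)) \
            == sorted(truth.planted_fnirs)


class TestAssociationStrength:
    @pytest.mark.parametrize("rho,label,sign", [
        (0.2, "small", "positive"),
        (-0.4, "medium", "negative"),
        (1.0, "large", "positive"),
        (0.05, "negligible", "positive"),
        (0.0, "negligible", "zero"),
        (0.3, "medium", "positive"),      # lower edges belong to upper bin
        (0.5, "large", "positive"),
        (-0.1, "small", "negative"),
    ])
    def test_bins(self, rho, label, sign):
        assert association_strength(rho) == (label, sign)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            association_strength(1.2)


def test_hemisphere_group_validation():
    with pytest.raises(ValueError):
        HemisphereGroup("middle", ("a",))
    with pytest.raises(ValueError):
        HemisphereGroup("left", ())
    with pytest.raises(ValueError):
        HemisphereGroup("left", ("a", "a"))
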