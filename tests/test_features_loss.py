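"""Feature assembly, symmetrization, cropping and the focal loss."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from c2contact.fixtures import FixtureSpec, target_features
from c2contact.model import (FocalLossConfig, focal_loss, focal_loss_grad,
                             random_crop, symmetrize_labels,
                             symmetrize_pairwise)
from c2contact.model.features import FeatureBundle
from c2contact.structures import ContactMap


@pytest.fixture(scope="module")
def small_target():
    spec = FixtureSpec(n_residues=30, seed=21, interface_pairs=((4, 12),),
                       msa_depth=80)
    return target_features(spec, dock_interval=60.0, dock_top_t=10)


class TestBuildFeatures:
    def test_shapes(self, small_target):
        bundle, labels, _, _ = small_target
        assert bundle.seq_features.shape == (30, 31)
        assert bundle.pair_features.shape == (4, 30, 30)
        assert labels.values.shape == (30, 30)

    def test_pair_channels_symmetric(self, small_target):
        bundle, _, _, _ = small_target
        for c in range(4):
            ch = bundle.pair_features[c]
            assert np.allclose(ch, ch.T)

    def test_distance_channel_normalized_zero_diagonal(self, small_target):
        bundle, _, _, _ = small_target
        dist = bundle.pair_features[0]
        assert np.allclose(np.diag(dist), 0.0)
        assert dist.min() >= 0 and dist.max() <= 1.0

    def test_length_mismatch_names_input(self, small_target):
        from c2contact.coupling import CouplingScores
        from c2contact.dockmap import DockingMap
        from c2contact.model.features import build_features
        from c2contact.msa import MSA, pssm as build_pssm
        from c2contact.structures import intra_distance_map
        _, _, dimer, _ = small_target
        bad_pssm = build_pssm(MSA(["ACDE"]))
        with pytest.raises(ValueError, match="pssm"):
            build_features(dimer.chain_a, bad_pssm, ["-"] * 30,
                           np.zeros((30, 3)),
                           intra_distance_map(dimer.chain_a),
                           DockingMap(np.zeros((30, 30)), 0),
                           CouplingScores(np.zeros((30, 30)),
                                          np.zeros((30, 30))))


class TestSymmetrize:
    def test_pairwise_fixed_point(self):
        X = np.array([[1.0, 2.0], [2.0, 3.0]])
        assert np.array_equal(symmetrize_pairwise(X), X)

    def test_pairwise_hand_example(self):
        X = np.array([[0.0, 2.0], [0.0, 0.0]])
        assert np.array_equal(symmetrize_pairwise(X),
                              np.array([[0.0, 1.0], [1.0, 0.0]]))

    @given(st.integers(2, 50), st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_pairwise_exactly_symmetric(self, L, seed):
        X = np.random.default_rng(seed).normal(size=(L, L))
        Y = symmetrize_pairwise(X)
        assert np.array_equal(Y, Y.T)

    def test_labels_or_with_transpose(self):
        Y = np.zeros((6, 6), dtype=int)
        Y[2, 5] = 1
        out = symmetrize_labels(Y)
        assert out[2, 5] == 1 and out[5, 2] == 1
        assert out.sum() == 2

    def test_labels_reject_non_binary(self):
        with pytest.raises(ValueError, match="binary"):
            symmetrize_labels(np.full((3, 3), 0.5))

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            symmetrize_pairwise(np.zeros((3, 4)))


class TestFocalLoss:
    def _oracle(self, p, y, alpha, gamma):
        # independent scalar evaluation, written directly from the definition
        import math
        if y == 1:
            return -alpha * (1 - p) ** gamma * math.log(p)
        return -(1 - alpha) * p ** gamma * math.log(1 - p)

    def test_hand_value(self):
        # p=0.5, y=1: 0.25 * 0.5^1.5 * ln 2
        got = focal_loss(np.array([[0.5]]), np.array([[1]]))
        assert got == pytest.approx(0.25 * 0.5 ** 1.5 * np.log(2), abs=1e-12)
        assert got == pytest.approx(0.0613, abs=1e-4)

    def test_perfect_prediction_vanishes(self):
        got = focal_loss(np.array([[1 - 1e-9]]), np.array([[1]]))
        assert got < 1e-8

    def test_matches_scalar_oracle_on_grid(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, size=(40, 40))
        y = (rng.random((40, 40)) < 0.3).astype(int)
        expected = np.mean([self._oracle(p[i, j], y[i, j], 0.25, 1.5)
                            for i in range(40) for j in range(40)])
        assert focal_loss(p, y) == pytest.approx(expected, abs=1e-10)

    def test_gamma_zero_is_weighted_bce(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.05, 0.95, size=(20, 20))
        y = (rng.random((20, 20)) < 0.5).astype(int)
        cfg = FocalLossConfig(alpha=0.25, gamma=0.0)
        bce = -np.mean(np.where(y == 1, 0.25 * np.log(p),
                                0.75 * np.log(1 - p)))
        assert focal_loss(p, y, cfg=cfg) == pytest.approx(bce, abs=1e-10)

    def test_masked_pairs_never_contribute(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.1, 0.9, size=(10, 10))
        y = (rng.random((10, 10)) < 0.2).astype(int)
        mask = rng.random((10, 10)) < 0.7
        base = focal_loss(p, y, mask)
        p2 = p.copy()
        p2[~mask] = 0.5  # arbitrary perturbation at masked entries
        assert focal_loss(p2, y, mask) == base
        g = focal_loss_grad(p, y, mask)
        assert np.all(g[~mask] == 0)

    def test_probability_guard(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[0.0]]), np.array([[1]]))

    def test_gradient_matches_finite_difference(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.2, 0.8, size=(5, 5))
        y = (rng.random((5, 5)) < 0.5).astype(int)
        g = focal_loss_grad(p, y)
        eps = 1e-7
        for (i, j) in [(0, 0), (2, 3), (4, 4)]:
            p1, p2 = p.copy(), p.copy()
            p1[i, j] += eps
            p2[i, j] -= eps
            num = (focal_loss(p1, y) - focal_loss(p2, y)) / (2 * eps)
            assert g[i, j] == pytest.approx(num, rel=1e-5)


class TestRandomCrop:
    def _bundle(self, L):
        rng = np.random.default_rng(L)
        return (FeatureBundle(rng.normal(size=(L, 31)),
                              rng.normal(size=(4, L, L)), np.ones((L, L), bool)),
                ContactMap((rng.random((L, L)) < 0.1).astype(np.uint8),
                           np.ones((L, L), bool)))

    def test_short_sequence_untouched(self):
        bundle, labels = self._bundle(300)
        out_b, out_l = random_crop(bundle, labels, max_len=400, rng=0)
        assert out_b is bundle and out_l is labels

    def test_long_sequence_cropped_consistently(self):
        bundle, labels = self._bundle(500)
        out_b, out_l = random_crop(bundle, labels, max_len=400, rng=7)
        assert out_b.seq_features.shape == (400, 31)
        assert out_b.pair_features.shape == (4, 400, 400)
        assert out_l.values.shape == (400, 400)
        # window applied identically to both axes: find the offset
        offsets = [s for s in range(101)
                   if np.array_equal(bundle.seq_features[s:s + 400],
                                     out_b.seq_features)]
        assert len(offsets) == 1
        s = offsets[0]
        assert np.array_equal(bundle.pair_features[:, s:s + 400, s:s + 400],
                              out_b.pair_features)

    def test_seed_reproducibility(self):
        bundle, labels = self._bundle(450)
        a, _ = random_crop(bundle, labels, max_len=400, rng=42)
        b, _ = random_crop(bundle, labels, max_len=400, rng=42)
        assert np.array_equal(a.seq_features, b.seq_features)

    def test_bad_max_len(self):
        bundle, labels = self._bundle(10)
        with pytest.raises(ValueError):
            random_crop(bundle, labels, max_len=0)
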