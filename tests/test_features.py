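import numpy as np
import pytest

from mcmf.channels import ChannelStack
from mcmf.errors import ParameterError
from mcmf.features import (
    FEATURE_NAMES,
    N_FEATURES,
    assemble_features,
    candidate_channel_stats,
    contextual_feature,
    features_to_frame,
    frame_to_features,
    global_stats,
    normalize_features,
)
from mcmf.preprocess import FovMask, PreprocessedImage
from mcmf.superpixels import Candidate


def _stack_from(arrs):
    return ChannelStack(channels=tuple(np.asarray(a, dtype=np.float64) for a in arrs))


def _candidate(coords, label=0, neighbors=(), barycenter=None, area=None):
    coords = np.asarray(coords)
    if barycenter is None:
        barycenter = tuple(coords.mean(axis=0))
    return Candidate(
        label=label,
        pixel_coords=coords,
        barycenter=barycenter,
        area=area if area is not None else len(coords),
        neighbor_ids=frozenset(neighbors),
    )


def _toy_candidates():
    """3-candidate toy: av_G = (0.2, 0.5, 0.5), global mean 0.5,
    barycenters (0,0), (0,10), (10,0), all mutual neighbours, N_1 = 4 px."""
    g = np.full((24, 24), 0.5)
    g[0, :4] = 0.2
    c1 = _candidate([[0, k] for k in range(4)], label=0, neighbors={1, 2},
                    barycenter=(0.0, 0.0))
    c2 = _candidate([[2, k] for k in range(4)], label=1, neighbors={0, 2},
                    barycenter=(0.0, 10.0))
    c3 = _candidate([[4, k] for k in range(4)], label=2, neighbors={0, 1},
                    barycenter=(10.0, 0.0))
    fov = FovMask(np.ones((24, 24), bool))
    # global mean: 576 px, 4 at 0.2 -> adjust 4 pixels up to keep mean 0.5
    g[23, :4] = 0.8
    return [c1, c2, c3], g, fov


def _oracle_context(cands, av, av_global, bary, denominator="pixels"):
    """Independent scripted evaluation of the contextual score."""
    out = []
    for i, c in enumerate(cands):
        total = 0.0
        for j in sorted(c.neighbor_ids):
            d2 = (bary[i][0] - bary[j][0]) ** 2 + (bary[i][1] - bary[j][1]) ** 2
            diff2 = (av[i] - av[j]) ** 2
            d1 = diff2 if av[i] <= av[j] else -diff2
            total += (av[i] / av_global) * d1 / d2
        denom = c.area if denominator == "pixels" else max(len(c.neighbor_ids), 1)
        out.append(total / denom)
    return np.array(out)


class TestChannelStats:
    def test_single_pixel(self):
        stack = _stack_from([np.full((4, 4), 0.3)] * 7)
        cand = _candidate([[1, 1]])
        stats = candidate_channel_stats(stack, cand)
        np.testing.assert_allclose(stats, 0.3)

    def test_hand_computed_four_values(self):
        ch = np.zeros((2, 4))
        ch[0] = [0.1, 0.2, 0.3, 0.4]
        stack = _stack_from([ch] * 7)
        cand = _candidate([[0, 0], [0, 1], [0, 2], [0, 3]])
        stats = candidate_channel_stats(stack, cand)
        np.testing.assert_allclose(stats[:4], [0.4, 0.1, 0.25, 0.25], atol=1e-15)

    def test_matches_naive_loop_oracle(self, rng):
        stack = _stack_from([rng.uniform(size=(16, 16)) for _ in range(7)])
        pts = rng.choice(256, size=20, replace=False)
        coords = np.stack([pts // 16, pts % 16], axis=1)
        cand = _candidate(coords)
        got = candidate_channel_stats(stack, cand)
        for i in range(7):
            vals = sorted(stack[i][r, c] for r, c in coords)
            assert got[4 * i + 0] == pytest.approx(max(vals), abs=1e-12)
            assert got[4 * i + 1] == pytest.approx(min(vals), abs=1e-12)
            assert got[4 * i + 2] == pytest.approx(sum(vals) / len(vals), abs=1e-12)
            mid = (vals[9] + vals[10]) / 2
            assert got[4 * i + 3] == pytest.approx(mid, abs=1e-12)


class TestGlobalStats:
    def _pre(self, green):
        rgb = np.stack([green] * 3, axis=-1)
        return PreprocessedImage(
            rgb_enhanced=rgb, green_enhanced=green, green_raw=green, clahe_gray=green
        )

    def test_constant(self):
        pre = self._pre(np.full((8, 8), 0.5))
        mean, std = global_stats(pre, FovMask(np.ones((8, 8), bool)))
        assert (mean, std) == (0.5, 0.0)

    def test_half_zero_half_one(self):
        g = np.zeros((8, 8))
        g[:4] = 1.0
        mean, std = global_stats(self._pre(g), FovMask(np.ones((8, 8), bool)))
        assert mean == pytest.approx(0.5)
        assert std == pytest.approx(0.5)  # population std

    def test_matches_loop_oracle(self, rng):
        g = rng.uniform(size=(16, 16))
        mask = rng.random((16, 16)) > 0.4
        mean, std = global_stats(self._pre(g), FovMask(mask))
        vals = [g[r, c] for r in range(16) for c in range(16) if mask[r, c]]
        m = sum(vals) / len(vals)
        v = sum((x - m) ** 2 for x in vals) / len(vals)
        assert mean == pytest.approx(m, abs=1e-12)
        assert std == pytest.approx(v**0.5, abs=1e-12)


class TestContextualFeature:
    def test_no_neighbors_zero(self):
        g = np.full((8, 8), 0.5)
        cand = _candidate([[0, 0]], neighbors=())
        s = contextual_feature([cand], g, FovMask(np.ones((8, 8), bool)))
        assert s[0] == 0.0

    def test_dark_candidate_positive_bright_negative(self):
        g = np.full((8, 8), 0.5)
        g[0, 0] = 0.2
        dark = _candidate([[0, 0]], label=0, neighbors={1}, barycenter=(0.0, 0.0))
        other = _candidate([[4, 4]], label=1, neighbors={0}, barycenter=(4.0, 4.0))
        s = contextual_feature([dark, other], g, FovMask(np.ones((8, 8), bool)))
        assert s[0] > 0  # darker than neighbour
        assert s[1] < 0  # brighter than neighbour

    def test_three_candidate_worked_example(self):
        cands, g, fov = _toy_candidates()
        s = contextual_feature(cands, g, fov, denominator="pixels")
        # hand computation: (0.2/0.5) * (0.09/100 + 0.09/100) / 4 = 1.8e-4
        assert s[0] == pytest.approx(1.8e-4, rel=1e-12)

    def test_matches_scripted_oracle(self, rng):
        n = 8
        g = rng.uniform(0.3, 0.7, size=(32, 32))
        cands = []
        bary = []
        for i in range(n):
            coords = np.stack(
                [rng.integers(0, 32, size=5), rng.integers(0, 32, size=5)], axis=1
            )
            b = (float(rng.uniform(0, 31)), float(rng.uniform(0, 31)))
            bary.append(b)
            neighbors = set(range(n)) - {i}
            cands.append(_candidate(coords, label=i, neighbors=neighbors, barycenter=b))
        fov = FovMask(np.ones((32, 32), bool))
        av = [g[c.pixel_coords[:, 0], c.pixel_coords[:, 1]].mean() for c in cands]
        av_global = g.mean()
        for denom in ("pixels", "neighbors"):
            got = contextual_feature(cands, g, fov, denominator=denom)
            want = _oracle_context(cands, av, av_global, bary, denom)
            np.testing.assert_allclose(got, want, atol=1e-14)

    def test_translation_invariance(self):
        cands, g, fov = _toy_candidates()
        shifted = [
            _candidate(
                c.pixel_coords, label=c.label, neighbors=c.neighbor_ids,
                barycenter=(c.barycenter[0] + 5.0, c.barycenter[1] - 3.0),
            )
            for c in cands
        ]
        s0 = contextual_feature(cands, g, fov)
        s1 = contextual_feature(shifted, g, fov)
        np.testing.assert_allclose(s0, s1, atol=1e-15)

    def test_coordinate_scaling_inverse_square(self):
        cands, g, fov = _toy_candidates()
        scaled = [
            _candidate(
                c.pixel_coords, label=c.label, neighbors=c.neighbor_ids,
                barycenter=(2.0 * c.barycenter[0], 2.0 * c.barycenter[1]),
            )
            for c in cands
        ]
        s0 = contextual_feature(cands, g, fov)
        s1 = contextual_feature(scaled, g, fov)
        np.testing.assert_allclose(s1, s0 / 4.0, atol=1e-15)

    def test_coincident_barycenters_warn_and_skip(self):
        g = np.full((8, 8), 0.5)
        a = _candidate([[0, 0]], label=0, neighbors={1}, barycenter=(1.0, 1.0))
        b = _candidate([[4, 4]], label=1, neighbors={0}, barycenter=(1.0, 1.0))
        with pytest.warns(UserWarning, match="barycenter"):
            s = contextual_feature([a, b], g, FovMask(np.ones((8, 8), bool)))
        np.testing.assert_array_equal(s, [0.0, 0.0])


class TestAssembleAndNormalize:
    def test_assemble_length_31(self):
        vec = assemble_features(np.zeros(28), (0.0, 0.0), 0.0)
        assert vec.shape == (N_FEATURES,) == (31,)

    def test_assemble_order(self):
        vec = assemble_features(np.arange(28.0), (100.0, 200.0), 300.0)
        np.testing.assert_array_equal(vec[:28], np.arange(28.0))
        assert vec[28] == 100.0 and vec[29] == 200.0 and vec[30] == 300.0

    def test_normalize_zero_mean_unit_var(self, rng):
        X = rng.normal(2.0, 3.0, size=(50, 31))
        Xn, (mu, sigma) = normalize_features(X)
        np.testing.assert_allclose(Xn.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Xn.var(axis=0), 1.0, atol=1e-9)

    def test_constant_column_flagged(self, rng):
        X = rng.normal(size=(10, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            Xn, _ = normalize_features(X)
        np.testing.assert_array_equal(Xn[:, 1], 0.0)

    def test_reuse_training_stats(self, rng):
        X = rng.normal(size=(20, 5))
        _, stats = normalize_features(X)
        x_new = rng.normal(size=(1, 5))
        got, _ = normalize_features(x_new, stats=stats)
        mu, sigma = stats
        np.testing.assert_allclose(got, (x_new - mu) / sigma, atol=1e-12)

    def test_dimension_mismatch_error(self, rng):
        _, stats = normalize_features(rng.normal(size=(5, 4)))
        with pytest.raises(ParameterError):
            normalize_features(rng.normal(size=(5, 3)), stats=stats)

    def test_csv_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(6, 31))
        df = features_to_frame(X, range(6), image_id="img0", labels=[0, 1] * 3)
        path = tmp_path / "features.csv"
        df.to_csv(path, index=False)
        import pandas as pd

        loaded, labels = frame_to_features(pd.read_csv(path))
        np.testing.assert_allclose(loaded, X, atol=1e-9)
        np.testing.assert_array_equal(labels, [0, 1] * 3)

    def test_feature_names_unique(self):
        assert len(set(FEATURE_NAMES)) == 31
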