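import numpy as np
import pytest

from rsfmripost.io import BrainMask, TimeSeriesMatrix, volume_to_matrix
from rsfmripost.spon import (
    MetricMap,
    NeighborScheme,
    PackedAdjacency,
    alff_falff,
    amplitude,
    fcd,
    fcs,
    fisher_z,
    kendall_w,
    normalize_map,
    reho,
)
from rsfmripost.synthetic import PhantomSpec, blob_mask, full_mask, \
    generate_phantom, sinusoid, white_noise


def line_matrix(values, tr=2.0):
    """Arrange columns as a 1D line of voxels (all mutually adjacent pairs
    only along x)."""
    values = np.asarray(values, dtype=np.float64)
    V = values.shape[1]
    return TimeSeriesMatrix(values, np.arange(V), tr=tr, source_shape=(V, 1, 1))


def line_mask(V):
    return BrainMask(np.ones((V, 1, 1), dtype=bool), np.diag([3.0, 3, 3, 1]))


def brute_force_w(series):
    """Independent Kendall's W oracle: explicit per-frame rank sums.

    Ranks computed by counting comparisons (midranks for ties), never by
    scipy; the formula evaluated term by term.
    """
    series = np.asarray(series, dtype=np.float64)
    n, K = series.shape
    ranks = np.empty_like(series)
    for j in range(K):
        col = series[:, j]
        for i in range(n):
            less = np.sum(col < col[i])
            equal = np.sum(col == col[i])
            ranks[i, j] = less + (equal + 1) / 2.0  # midrank
    R = [float(ranks[i].sum()) for i in range(n)]
    R_bar = sum(R) / n
    numer = sum(r**2 for r in R) - n * R_bar**2
    denom = (1.0 / 12.0) * K**2 * (n**3 - n)
    return numer / denom


class TestNormalize:
    def _map(self, values, mask):
        return MetricMap(np.asarray(values, dtype=float, order="F"), mask)

    def test_zscore_moments(self, rng):
        mask = BrainMask(np.ones((4, 4, 4), dtype=bool), np.eye(4))
        m = self._map(rng.normal(5, 2, (4, 4, 4)), mask)
        out = normalize_map(m, mode="zscore")
        vals = out.in_mask()
        assert abs(vals.mean()) < 1e-12
        assert vals.std() == pytest.approx(1.0, abs=1e-12)

    def test_mean_mode_maps_constant_to_one(self):
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool), np.eye(4))
        out = normalize_map(self._map(np.full((3, 3, 3), 5.0), mask), mode="mean")
        np.testing.assert_allclose(out.in_mask(), 1.0)

    def test_constant_map_zscore_errors(self):
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool), np.eye(4))
        with pytest.raises(ValueError, match="sd is zero"):
            normalize_map(self._map(np.full((3, 3, 3), 5.0), mask), mode="zscore")

    def test_zero_mean_map_mean_mode_errors(self):
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool), np.eye(4))
        with pytest.raises(ValueError, match="mean is zero"):
            normalize_map(self._map(np.zeros((3, 3, 3)), mask), mode="mean")


class TestAmplitude:
    def test_constant_series_zero(self):
        mat = line_matrix(np.full((10, 3), 4.0))
        am_mean, am_std = amplitude(mat, line_mask(3))
        np.testing.assert_array_equal(am_mean.in_mask(), 0.0)
        np.testing.assert_array_equal(am_std.in_mask(), 0.0)

    def test_hand_case_alternating_signs(self):
        mat = line_matrix(np.array([[1.0], [-1.0], [1.0], [-1.0]]))
        am_mean, am_std = amplitude(mat, line_mask(1))
        assert am_mean.in_mask()[0] == pytest.approx(1.0)
        assert am_std.in_mask()[0] == pytest.approx(np.sqrt(4.0 / 3.0))

    def test_homogeneity_under_scaling(self, rng):
        x = rng.normal(size=(20, 4))
        m1, s1 = amplitude(line_matrix(x), line_mask(4))
        m2, s2 = amplitude(line_matrix(-2.5 * x), line_mask(4))
        np.testing.assert_allclose(m2.in_mask(), 2.5 * m1.in_mask())
        np.testing.assert_allclose(s2.in_mask(), 2.5 * s1.in_mask())


class TestAlff:
    def test_linearity_in_amplitude(self, rng):
        x = rng.normal(size=(100, 3))
        a1, _ = alff_falff(line_matrix(x), line_mask(3))
        a2, _ = alff_falff(line_matrix(2 * x), line_mask(3))
        np.testing.assert_allclose(a2.in_mask(), 2 * a1.in_mask(), rtol=1e-10)

    def test_pure_in_band_signal_has_falff_near_one(self):
        spec = PhantomSpec(dims=(3, 3, 3), n_frames=200, tr=2.0,
                           components=[("global", sinusoid(0.05, 2.0)),
                                       ("global", sinusoid(0.03, 1.0))],
                           seed=0)
        vol = generate_phantom(spec)
        mask = full_mask((3, 3, 3))
        _, falff = alff_falff(volume_to_matrix(vol, mask), mask)
        assert np.all(falff.in_mask() > 0.98)

    def test_white_noise_falff_matches_band_fraction(self, rng):
        """Flat spectrum: mean fALFF ~ fraction of bins inside the band."""
        T, tr = 200, 2.0
        x = rng.normal(size=(T, 1000))
        mat = line_matrix(x, tr=tr)
        _, falff = alff_falff(mat, line_mask(1000), band=(0.01, 0.08))
        freqs = np.fft.rfftfreq(T, tr)
        q = np.sum((freqs >= 0.01) & (freqs <= 0.08)) / np.sum(freqs > 0)
        vals = falff.in_mask()
        sem = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - q) < 3 * sem + 1e-3

    def test_time_reversal_invariance(self, rng):
        x = rng.normal(size=(80, 5))
        a1, f1 = alff_falff(line_matrix(x), line_mask(5))
        a2, f2 = alff_falff(line_matrix(x[::-1]), line_mask(5))
        np.testing.assert_allclose(a1.in_mask(), a2.in_mask(), rtol=1e-10)
        np.testing.assert_allclose(f1.in_mask(), f2.in_mask(), rtol=1e-10)

    def test_empty_band_errors(self, rng):
        mat = line_matrix(rng.normal(size=(10, 2)), tr=2.0)
        with pytest.raises(ValueError, match="bins"):
            alff_falff(mat, line_mask(2), band=(0.011, 0.012))


class TestReho:
    def test_identical_series_give_w_one(self):
        base = np.sin(np.linspace(0, 6, 30))
        mat = line_matrix(np.tile(base[:, None], (1, 5)))
        w = reho(mat, line_mask(5), scheme="face")
        np.testing.assert_allclose(w.in_mask(), 1.0, atol=1e-12)

    def test_hand_case_rank_matrix(self):
        # 3 series whose temporal ranks are [1,2,3], [1,2,3], [2,1,3]:
        # rank sums per frame 4, 5, 9 -> W = 14/18
        series = np.array([
            [10.0, 100.0, 5.0],
            [20.0, 200.0, 4.0],
            [30.0, 300.0, 9.0],
        ])
        expected = brute_force_w(series)
        assert expected == pytest.approx(14.0 / 18.0)
        assert kendall_w(series) == pytest.approx(expected)
        # middle voxel of a 3-voxel line has exactly these K=3 members
        mat = line_matrix(series)
        w = reho(mat, line_mask(3), scheme="face")
        assert w.in_mask()[1] == pytest.approx(expected)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 30))
            K = int(rng.integers(2, 28))
            series = rng.normal(size=(n, K))
            if rng.random() < 0.3:
                series = np.round(series)  # provoke ties -> midranks
            assert kendall_w(series) == pytest.approx(
                brute_force_w(series), abs=1e-12)

    def test_boundary_shrinks_neighborhood(self):
        """End voxel of a line has K=2; W must use the actual K."""
        series = np.array([[1.0, 5.0], [2.0, 4.0], [3.0, 6.0]])
        mat = line_matrix(series)
        w = reho(mat, line_mask(2), scheme="face")
        assert w.in_mask()[0] == pytest.approx(brute_force_w(series))

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=(40, 6))
        w1 = reho(line_matrix(x), line_mask(6), scheme="face").in_mask()
        w2 = reho(line_matrix(np.exp(x)), line_mask(6), scheme="face").in_mask()
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_w_in_unit_interval(self, rng):
        x = rng.normal(size=(25, 30))
        mat = TimeSeriesMatrix(
            x, np.arange(30), tr=2.0, source_shape=(5, 3, 2))
        mask = BrainMask(np.ones((5, 3, 2), dtype=bool), np.eye(4))
        w = reho(mat, mask, scheme="vertex").in_mask()
        assert np.all((w >= 0) & (w <= 1))

    def test_constant_neighborhood_warns_and_zero(self):
        mat = line_matrix(np.full((10, 3), 2.0))
        with pytest.warns(UserWarning, match="constant"):
            w = reho(mat, line_mask(3), scheme="face")
        np.testing.assert_array_equal(w.in_mask(), 0.0)

    def test_scheme_sizes(self):
        assert NeighborScheme("face").k_total == 7
        assert NeighborScheme("edge").k_total == 19
        assert NeighborScheme("vertex").k_total == 27


class TestFcd:
    def test_one_blob_construction(self, one_blob_phantom):
        vol, mask, blob = one_blob_phantom
        mat = volume_to_matrix(vol, mask)
        lf, gf, lrf = fcd(mat, mask, r_threshold=0.6)
        seed_lin = np.flatnonzero(blob.ravel(order="F"))[0]
        assert gf.values.ravel(order="F")[seed_lin] == 9
        assert lf.values.ravel(order="F")[seed_lin] == 9
        assert lrf.values.ravel(order="F")[seed_lin] == 0

    def test_two_blob_construction(self, two_blob_phantom):
        vol, mask, blob_a, blob_b = two_blob_phantom
        mat = volume_to_matrix(vol, mask)
        lf, gf, lrf = fcd(mat, mask, r_threshold=0.6)
        seed_lin = np.flatnonzero(blob_a.ravel(order="F"))[0]
        assert gf.values.ravel(order="F")[seed_lin] == 8
        assert lf.values.ravel(order="F")[seed_lin] == 4
        assert lrf.values.ravel(order="F")[seed_lin] == 4

    def test_independent_noise_high_threshold_all_zero(self, rng):
        mat = TimeSeriesMatrix(rng.normal(size=(100, 27)), np.arange(27),
                               tr=2.0, source_shape=(3, 3, 3))
        mask = BrainMask(np.ones((3, 3, 3), dtype=bool), np.eye(4))
        lf, gf, lrf = fcd(mat, mask, r_threshold=0.99)
        for m in (lf, gf, lrf):
            np.testing.assert_array_equal(m.in_mask(), 0.0)

    def test_packed_equals_dense(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            mat = TimeSeriesMatrix(r.normal(size=(40, 60)), np.arange(60),
                                   tr=2.0, source_shape=(5, 4, 3))
            mask = BrainMask(np.ones((5, 4, 3), dtype=bool), np.eye(4))
            packed = fcd(mat, mask, r_threshold=0.3, packed=True)
            dense = fcd(mat, mask, r_threshold=0.3, packed=False)
            for mp, md in zip(packed, dense):
                np.testing.assert_array_equal(mp.values, md.values)

    def test_decomposition_identity_and_rescaling_invariance(self, rng):
        x = rng.normal(size=(60, 48))
        mat = TimeSeriesMatrix(x, np.arange(48), tr=2.0, source_shape=(4, 4, 3))
        mask = BrainMask(np.ones((4, 4, 3), dtype=bool), np.eye(4))
        lf, gf, lrf = fcd(mat, mask, r_threshold=0.2)
        np.testing.assert_array_equal(gf.values, lf.values + lrf.values)
        assert np.all(lrf.in_mask() >= 0)
        scales = rng.uniform(0.5, 3.0, size=48)
        offsets = rng.normal(size=48)
        mat2 = TimeSeriesMatrix(x * scales + offsets, np.arange(48), tr=2.0,
                                source_shape=(4, 4, 3))
        lf2, gf2, lrf2 = fcd(mat2, mask, r_threshold=0.2)
        np.testing.assert_array_equal(gf.values, gf2.values)
        np.testing.assert_array_equal(lf.values, lf2.values)

    def test_packed_storage_is_one_thirty_second_of_float32(self):
        adj = np.zeros((1024, 1024), dtype=bool)
        store = PackedAdjacency.from_bool(adj)
        dense_float32 = adj.shape[0] * adj.shape[1] * 4
        assert store.nbytes * 32 == dense_float32

    def test_zero_variance_seed_warns(self):
        x = np.random.default_rng(0).normal(size=(30, 4))
        x[:, 2] = 5.0
        mat = line_matrix(x)
        with pytest.warns(UserWarning, match="zero-variance"):
            lf, gf, lrf = fcd(mat, line_mask(4), r_threshold=0.5)
        assert gf.in_mask()[2] == 0


class TestFcs:
    def test_threshold_above_everything_gives_zero(self, rng):
        mat = line_matrix(rng.normal(size=(50, 5)))
        out = fcs(mat, line_mask(5), threshold=10.0)
        np.testing.assert_array_equal(out.in_mask(), 0.0)

    def test_matches_brute_force_on_toy_system(self, rng):
        x = rng.normal(size=(60, 4))
        x[:, 1] += 0.9 * x[:, 0]
        x[:, 3] += 0.5 * x[:, 2]
        thr = 0.3
        out = fcs(line_matrix(x), line_mask(4), threshold=thr).in_mask()
        # brute force straight from the definition
        for i in range(4):
            acc = 0.0
            for j in range(4):
                if j == i:
                    continue
                r = np.corrcoef(x[:, i], x[:, j])[0, 1]
                z = 0.5 * np.log((1 + r) / (1 - r))
                if z > thr:
                    acc += z
            assert out[i] == pytest.approx(acc / 3.0, abs=1e-10)

    def test_uncorrelated_voxel_scales_by_denominator(self, rng):
        x = rng.normal(size=(500, 4))
        x[:, 1] += 1.5 * x[:, 0]
        x[:, 3] += 1.5 * x[:, 2]
        thr = 0.5
        base = fcs(line_matrix(x), line_mask(4), threshold=thr).in_mask()
        extra = rng.normal(size=(500, 1)) * 1e3  # uncorrelated, sub-threshold
        grown = fcs(line_matrix(np.hstack([x, extra])), line_mask(5),
                    threshold=thr).in_mask()
        np.testing.assert_allclose(grown[:4], base * 3.0 / 4.0, atol=1e-6)


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    def test_odd_symmetry(self):
        for r in np.arange(0.1, 1.0, 0.1):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_unit_correlation_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            z = fisher_z(1.0)
        assert np.isfinite(z)

    def test_magnitude_above_one_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.5)

    def test_strictly_monotone(self, rng):
        r = np.sort(rng.uniform(-0.99, 0.99, 50))
        z = fisher_z(r)
        assert np.all(np.diff(z) > 0)
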