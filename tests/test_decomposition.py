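"""Map vectorization, MDS/stress, PCA/ICA, alignment, sampling adequacy."""

import numpy as np
import pytest

from metafoci.foci_io import BrainGrid, Volume
from metafoci.decomposition import (
    MapMatrix,
    align_components,
    classical_mds_init,
    correlation_distance,
    ica_decompose,
    kruskal_stress,
    mds_embed,
    pca_decompose,
    sampling_adequacy,
    vectorize_maps,
)


@pytest.fixture(scope="module")
def grid():
    return BrainGrid.create((10, 10, 10), 4.0)


def _volumes(grid, values):
    vols = []
    for i, row in enumerate(values):
        data = np.zeros(grid.shape)
        data[grid.mask] = row
        vols.append(Volume(grid, data, name=f"m{i}"))
    return vols


def _matrix(grid, values, names=None):
    return MapMatrix(
        names=names or [f"m{i}" for i in range(len(values))],
        values=np.asarray(values, dtype=float),
        grid=grid,
    )


class TestVectorize:
    def test_shape_and_round_trip(self, grid):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(9, grid.n_mask_voxels))
        vols = _volumes(grid, vals)
        m = vectorize_maps(vols, grid)
        assert m.values.shape == (9, grid.n_mask_voxels)
        assert m.names == [f"m{i}" for i in range(9)]
        for i, v in enumerate(vols):
            np.testing.assert_array_equal(m.values[i], v.data[grid.mask])

    def test_zero_variance_flagged_and_rejected_downstream(self, grid):
        vals = np.vstack(
            [np.ones(grid.n_mask_voxels), np.arange(grid.n_mask_voxels, dtype=float)]
        )
        m = _matrix(grid, vals)
        assert m.zero_variance_maps() == ["m0"]
        with pytest.raises(ValueError, match="m0"):
            correlation_distance(m)

    def test_grid_mismatch(self, grid):
        other = BrainGrid.create((8, 8, 8), 4.0)
        v = Volume(other, np.zeros(other.shape))
        with pytest.raises(ValueError):
            vectorize_maps([v], grid)


class TestCorrelationDistance:
    def test_identical_and_negated(self, grid):
        rng = np.random.default_rng(1)
        x = rng.normal(size=grid.n_mask_voxels)
        m = _matrix(grid, [x, x.copy(), -x])
        d = correlation_distance(m)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(d, d.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-15)

    def test_matches_pairwise_loop(self, grid):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(5, 200))
        m = _matrix(grid, np.pad(vals, ((0, 0), (0, grid.n_mask_voxels - 200))))
        m.values[:, 200:] = rng.normal(size=(5, grid.n_mask_voxels - 200))
        d = correlation_distance(m)
        for i in range(5):
            for j in range(5):
                xi, xj = m.values[i], m.values[j]
                r = (
                    ((xi - xi.mean()) * (xj - xj.mean())).sum()
                    / np.sqrt(((xi - xi.mean()) ** 2).sum() * ((xj - xj.mean()) ** 2).sum())
                )
                assert d[i, j] == pytest.approx(1.0 - r, abs=1e-12)


class TestKruskalStress:
    def test_perfect_embedding_zero(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        assert kruskal_stress(d, pts) == pytest.approx(0.0, abs=1e-12)

    def test_collapsed_configuration_is_one(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        coords = np.zeros((5, 2))
        assert kruskal_stress(d, coords) == pytest.approx(1.0)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(5)
        d = np.abs(rng.normal(size=(4, 4)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        coords = rng.normal(size=(4, 2))
        num = den = 0.0
        for i in range(4):
            for j in range(i + 1, 4):
                dhat = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
                num += (d[i, j] - dhat) ** 2
                den += d[i, j] ** 2
        assert kruskal_stress(d, coords) == pytest.approx(
            np.sqrt(num / den), abs=1e-12
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            kruskal_stress(np.zeros((3, 3)), np.zeros((3, 2)))


class TestMds:
    def test_embeddable_distances_reach_zero_stress(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(9, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        emb = mds_embed(d, dims=3)
        assert emb.stress < 1e-6

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        emb = mds_embed(d, dims=2)
        assert emb.stress < 1e-6

    def test_dims_must_be_below_n(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            mds_embed(d, dims=3)

    def test_deterministic_given_init(self):
        rng = np.random.default_rng(7)
        d = np.abs(rng.normal(size=(7, 7)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        a = mds_embed(d, dims=2)
        b = mds_embed(d, dims=2)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)

    def test_higher_dims_no_worse(self):
        """S(3D) <= S(2D) with the nested classical initialization."""
        rng = np.random.default_rng(8)
        for _ in range(10):
            d = np.abs(rng.normal(size=(9, 9)))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            s2 = mds_embed(d, dims=2).stress
            s3 = mds_embed(d, dims=3).stress
            assert s3 <= s2 + 1e-9

    def test_classical_init_nested(self):
        rng = np.random.default_rng(9)
        d = np.abs(rng.normal(size=(6, 6)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        i2 = classical_mds_init(d, 2)
        i3 = classical_mds_init(d, 3)
        np.testing.assert_allclose(i3[:, :2], i2, atol=1e-10)


class TestPca:
    def test_proportional_maps_single_component(self, grid):
        rng = np.random.default_rng(10)
        x = rng.normal(size=grid.n_mask_voxels)
        m = _matrix(grid, [x, 2 * x, -0.5 * x])
        dec = pca_decompose(m, 3)
        assert dec.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_planted_mixture_recovery(self, grid):
        rng = np.random.default_rng(11)
        n = grid.n_mask_voxels
        src = np.linalg.qr(rng.normal(size=(n, 3)))[0][:, :3].T  # orthogonal sources
        # orthogonal mixing columns with separated scales so the components
        # are identifiable (no eigenvalue degeneracy)
        mix = np.linalg.qr(rng.normal(size=(9, 3)))[0] @ np.diag([3.0, 2.0, 1.0])
        x = mix @ src + 1e-3 * rng.normal(size=(9, n))
        dec = pca_decompose(_matrix(grid, x), 3)
        assert dec.explained_variance_ratio.sum() > 0.99
        r = np.abs(np.corrcoef(src, dec.scores.T)[:3, 3:])
        assert (r.max(axis=1) > 0.95).all()

    def test_full_reconstruction(self, grid):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(5, grid.n_mask_voxels))
        m = _matrix(grid, x)
        dec = pca_decompose(m, 5)
        centred = (x.T - x.T.mean(axis=0)).T
        recon = (dec.scores @ dec.loadings.T).T
        assert np.abs(recon - centred).max() < 1e-8 * np.abs(centred).max()

    def test_k_validation(self, grid):
        m = _matrix(grid, np.random.default_rng(0).normal(size=(3, grid.n_mask_voxels)))
        with pytest.raises(ValueError):
            pca_decompose(m, 0)
        with pytest.raises(ValueError):
            pca_decompose(m, 4)


class TestIca:
    def test_two_uniform_sources_recovered(self, grid):
        rng = np.random.default_rng(13)
        n = grid.n_mask_voxels
        src = rng.uniform(-1, 1, size=(2, n))
        mix = np.array([[1.0, 0.4], [0.3, 1.0]])
        m = _matrix(grid, mix @ src)
        dec = ica_decompose(m, 2, seed=0)
        r = np.abs(np.corrcoef(src, dec.scores.T)[:2, 2:])
        assert (r.max(axis=1) > 0.99).all()

    def test_single_component(self, grid):
        rng = np.random.default_rng(14)
        n = grid.n_mask_voxels
        src = rng.uniform(-1, 1, size=(1, n))
        mix = rng.normal(size=(4, 1))
        m = _matrix(grid, mix @ src + 0.05 * rng.uniform(-1, 1, size=(4, n)))
        dec = ica_decompose(m, 1, seed=0)
        r = np.abs(np.corrcoef(src[0], dec.scores[:, 0])[0, 1])
        assert r > 0.99


class TestAlign:
    def test_identity_when_already_matched(self, grid):
        rng = np.random.default_rng(15)
        n = grid.n_mask_voxels
        src = rng.uniform(-1, 1, size=(4, n))
        mix = rng.normal(size=(9, 4))
        m = _matrix(grid, mix @ src)
        pca = pca_decompose(m, 4)
        fake_ica = pca_decompose(m, 4)
        fake_ica.method = "ica"
        aligned = align_components(fake_ica, pca)
        np.testing.assert_array_equal(aligned.order, np.arange(4))
        np.testing.assert_array_equal(aligned.signs, np.ones(4))

    def test_permutation_and_flip_recovered(self, grid):
        rng = np.random.default_rng(16)
        n = grid.n_mask_voxels
        src = rng.uniform(-1, 1, size=(4, n))
        mix = rng.normal(size=(9, 4))
        m = _matrix(grid, mix @ src)
        pca = pca_decompose(m, 4)
        perm = np.array([2, 0, 3, 1])
        flip = np.array([1.0, -1.0, 1.0, -1.0])
        shuffled = pca_decompose(m, 4)
        shuffled.method = "ica"
        shuffled.scores = pca.scores[:, perm] * flip
        shuffled.loadings = pca.loadings[:, perm] * flip
        aligned = align_components(shuffled, pca)
        np.testing.assert_allclose(aligned.scores, pca.scores, atol=1e-10)
        np.testing.assert_allclose(aligned.loadings, pca.loadings, atol=1e-10)

    def test_k_mismatch(self, grid):
        rng = np.random.default_rng(17)
        m = _matrix(grid, rng.normal(size=(5, grid.n_mask_voxels)))
        with pytest.raises(ValueError):
            align_components(pca_decompose(m, 2), pca_decompose(m, 3))


class TestSamplingAdequacy:
    def test_orthogonal_maps_bartlett_zero(self, grid):
        n = grid.n_mask_voxels
        # rows of an orthogonal basis: exactly uncorrelated maps
        q = np.linalg.qr(np.random.default_rng(18).normal(size=(n, 3)))[0][:, :3]
        q -= q.mean(axis=0)
        q = np.linalg.qr(q)[0][:, :3]
        m = _matrix(grid, q.T)
        kmo, chi2, df, p = sampling_adequacy(m)
        assert chi2 == pytest.approx(0.0, abs=1e-6)
        assert p == pytest.approx(1.0, abs=1e-9)
        assert df == 3

    def test_matches_textbook_formulas(self, grid):
        rng = np.random.default_rng(19)
        n = grid.n_mask_voxels
        x = rng.normal(size=(4, n))
        x[1] += 0.5 * x[0]
        x[3] += 0.3 * x[2]
        m = _matrix(grid, x)
        kmo, chi2, df, p = sampling_adequacy(m)
        r = np.corrcoef(x)
        # Bartlett
        chi2_ref = -(n - 1 - (2 * 4 + 5) / 6) * np.log(np.linalg.det(r))
        assert chi2 == pytest.approx(chi2_ref, abs=1e-10 * chi2_ref)
        assert df == 6
        # KMO via explicit partial correlations
        rinv = np.linalg.inv(r)
        partial = np.zeros_like(r)
        for i in range(4):
            for j in range(4):
                partial[i, j] = -rinv[i, j] / np.sqrt(rinv[i, i] * rinv[j, j])
        num = sum(r[i, j] ** 2 for i in range(4) for j in range(4) if i != j)
        den = num + sum(
            partial[i, j] ** 2 for i in range(4) for j in range(4) if i != j
        )
        assert kmo == pytest.approx(num / den, abs=1e-10)

    def test_needs_three_maps(self, grid):
        m = _matrix(grid, np.random.default_rng(0).normal(size=(2, grid.n_mask_voxels)))
        with pytest.raises(ValueError):
            sampling_adequacy(m)


class TestLeaveOneOutStability:
    def test_dropping_one_map_keeps_loadings(self, grid):
        """Removing one map leaves the retained maps' structure intact."""
        rng = np.random.default_rng(20)
        n = grid.n_mask_voxels
        src = rng.uniform(-1, 1, size=(4, n))
        mix = np.linalg.qr(rng.normal(size=(9, 4)))[0] @ np.diag([4.0, 3.0, 2.0, 1.0])
        x = mix @ src + 0.05 * rng.uniform(-1, 1, size=(9, n))
        full = pca_decompose(_matrix(grid, x), 4)
        reduced = pca_decompose(_matrix(grid, x[:-1]), 4)
        for c in range(4):
            r = np.abs(
                np.corrcoef(full.loadings[:-1, c], reduced.loadings[:, c])[0, 1]
            )
            assert r > 0.9
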