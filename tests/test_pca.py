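import numpy as np
import pandas as pd
import pytest

from conftest import make_connectome, random_connectome
from mesoconn.pca_profile import (
    FEATURES,
    feature_table,
    neighborhood_rings,
    parzen_density,
    pca,
)


def star(n_spokes=4):
    pairs = []
    for i in range(n_spokes):
        pairs += [("hub", f"s{i}"), (f"s{i}", "hub")]
    return make_connectome(["hub"] + [f"s{i}" for i in range(n_spokes)], pairs)


class TestFeatureTable:
    def test_complete_digraph_identical_rows(self, complete3):
        ft = feature_table(complete3)
        assert list(ft.columns) == FEATURES
        assert np.allclose(ft.to_numpy(), ft.to_numpy()[0])

    def test_star_hand_counts(self):
        ft = feature_table(star(4))
        assert ft.loc["hub", "DG_all"] == 8
        assert ft.loc["s0", "AvgDG_nb"] == 8  # sole neighbor is the hub
        assert ft.loc["s0", "VC_DG"] == 0     # single neighbor degree


class TestPCA:
    def test_collinear_data_single_component(self):
        t = np.linspace(0, 1, 10)
        df = pd.DataFrame({f: (i + 1) * t for i, f in enumerate(FEATURES)})
        res = pca(df)
        assert res.shares[0] == pytest.approx(100.0, abs=1e-9)

    def test_shares_sum_and_orthonormal_loadings(self):
        rng = np.random.default_rng(0)
        c = random_connectome(rng, 15, 0.3)
        res = pca(feature_table(c))
        assert res.shares.sum() == pytest.approx(100.0, abs=1e-6)
        gram = res.loadings.T @ res.loadings
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-10)

    def test_scores_match_spectral_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6))
        df = pd.DataFrame(x, columns=FEATURES)
        res = pca(df)
        z = (x - x.mean(0)) / x.std(0)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        oracle = z @ vt.T
        for j in range(2):
            col = res.scores[:, j]
            assert (np.allclose(col, oracle[:, j], atol=1e-8)
                    or np.allclose(col, -oracle[:, j], atol=1e-8))

    def test_sign_convention(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 6)), columns=FEATURES)
        res = pca(df)
        for j in range(res.loadings.shape[1]):
            col = res.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(20, 6)), columns=FEATURES)
        df["Loc"] = 0.5
        with pytest.warns(UserWarning):
            res = pca(df)
        assert "Loc" not in res.feature_names
        assert res.shares.sum() == pytest.approx(100.0, abs=1e-6)

    def test_isotropic_noise_equal_shares(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(20000, 6)), columns=FEATURES)
        res = pca(df)
        assert np.allclose(res.shares, 100 / 6, atol=1.0)

    def test_too_few_nodes(self):
        df = pd.DataFrame(np.ones((2, 6)), columns=FEATURES)
        with pytest.raises(ValueError):
            pca(df)


class TestParzen:
    def test_single_point_mode(self):
        xs, ys, d = parzen_density(np.array([[2.0, -1.0]]), bandwidth=0.5)
        iy, ix = np.unravel_index(np.argmax(d), d.shape)
        assert xs[ix] == pytest.approx(2.0, abs=0.1)
        assert ys[iy] == pytest.approx(-1.0, abs=0.1)

    def test_two_far_points_equal_maxima(self):
        pts = np.array([[0.0, 0.0], [20.0, 0.0]])
        xs, ys, d = parzen_density(pts, bandwidth=1.0, grid_spec=(201, 41))
        left = d[:, xs < 10].max()
        right = d[:, xs > 10].max()
        assert left == pytest.approx(right, rel=1e-6)

    def test_integral_near_one(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(30, 2))
        xs, ys, d = parzen_density(pts)
        integral = d.sum() * (xs[1] - xs[0]) * (ys[1] - ys[0])
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_invariant_under_point_order(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(15, 2))
        _, _, a = parzen_density(pts, bandwidth=0.7)
        _, _, b = parzen_density(pts[::-1], bandwidth=0.7)
        assert np.allclose(a, b)

    def test_bad_bandwidth(self):
        with pytest.raises(ValueError):
            parzen_density(np.zeros((3, 2)), bandwidth=-1.0)


class TestRings:
    def test_star_hub(self):
        r = neighborhood_rings(star(4), "hub")
        assert r.ring1 == {f"s{i}" for i in range(4)}
        assert r.ring2 == set()

    def test_chain(self):
        c = make_connectome("ABCD", [("A", "B"), ("B", "A"), ("B", "C"),
                                     ("C", "B"), ("C", "D"), ("D", "C")])
        r = neighborhood_rings(c, "A")
        assert r.ring1 == {"B"} and r.ring2 == {"C"}
        assert r.arcs_between_rings == 2  # B<->C

    def test_complete_no_second_ring(self, complete3):
        r = neighborhood_rings(complete3, "A")
        assert r.ring2 == set()
        assert r.arcs_within_ring1 == 2  # B<->C

    def test_unknown_region(self, complete3):
        with pytest.raises(KeyError):
            neighborhood_rings(complete3, "Z")
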