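import numpy as np
import pandas as pd
import pytest
import capscreen
from capscreen import embedding as emb

from .conftest import make_matrix


class TestEuclideanDistances:
    def test_metric_basics(self):
        profiles = pd.DataFrame(
            [[0.0, 0.0, 0.0], [0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [0.0, 0.0, 2.5]],
            index=["a", "b", "c", "d"],
        )
        d = emb.euclidean_distances(profiles)
        assert d.loc["a", "b"] == 0.0
        assert d.loc["a", "c"] == pytest.approx(5.0)  # 3-4-5 triangle
        assert d.loc["a", "d"] == pytest.approx(2.5)  # single-coordinate delta
        np.testing.assert_allclose(d.to_numpy(), d.to_numpy().T)
        assert np.diag(d.to_numpy()).sum() == 0.0

    def test_missing_values_rejected(self):
        profiles = pd.DataFrame([[1.0, np.nan], [0.0, 0.0]])
        with pytest.raises(ValueError, match="complete"):
            emb.euclidean_distances(profiles)


class TestClassicalMDS:
    def test_collinear_three_points_single_eigenvalue(self):
        """d12 = d23 = 1, d13 = 2 is realizable only on a line: exactly one
        eigenvalue of the double-centered matrix exceeds 1e-12."""
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        coords, eigvals = emb.classical_mds(pd.DataFrame(D), dims=3)
        assert (eigvals > 1e-12).sum() == 1
        assert coords.shape[1] == 1
        d = emb.embedding_distances(coords).to_numpy()
        np.testing.assert_allclose(d, D, atol=1e-9)

    def test_exact_recovery_of_3d_point_cloud(self):
        rng = np.random.default_rng(12)
        points = rng.normal(size=(40, 3))
        D = emb.euclidean_distances(pd.DataFrame(points))
        coords, eigvals = emb.classical_mds(D, dims=3)
        np.testing.assert_allclose(
            emb.embedding_distances(coords).to_numpy(), D.to_numpy(), atol=1e-9
        )

    def test_translation_invariance_of_spectrum(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(15, 4))
        D1 = emb.euclidean_distances(pd.DataFrame(points))
        D2 = emb.euclidean_distances(pd.DataFrame(points + 100.0))
        np.testing.assert_allclose(D1.to_numpy(), D2.to_numpy(), atol=1e-8)
        _, e1 = emb.classical_mds(D1)
        _, e2 = emb.classical_mds(D2)
        np.testing.assert_allclose(e1, e2, atol=1e-6)

    def test_deterministic_sign_canonicalization(self):
        rng = np.random.default_rng(9)
        D = emb.euclidean_distances(pd.DataFrame(rng.normal(size=(10, 3))))
        c1, _ = emb.classical_mds(D)
        c2, _ = emb.classical_mds(D.copy())
        pd.testing.assert_frame_equal(c1, c2)
        for col in c1.columns:
            v = c1[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_low_rank_warning(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        with pytest.warns(UserWarning, match="rank"):
            coords, _ = emb.classical_mds(D, dims=3)
        assert coords.shape[1] == 1


class TestProfileMatrix:
    def test_ncbp_registry_yields_57_dimensions(self, spiked_screen):
        """Profiles span one dimension per case IP; with the packaged NCBP
        registry the full screen would span 23 + 22 + 12 = 57 dimensions."""
        design = capscreen.read_design(capscreen.ncbp_design_path())
        n_case = sum(design.n_case_runs().values())
        assert n_case == 57
        # and on an analyzed synthetic screen, columns == its case runs
        sdesign, _, _, analysis = spiked_screen
        profiles = emb.build_profile_matrix(
            analysis.normalized_mean, sdesign, analysis.results, min_tests=1
        )
        assert list(profiles.columns) == sdesign.case_experiments("NCBP1")

    def test_min_tests_nesting(self, spiked_screen):
        design, _, _, analysis = spiked_screen
        p1 = emb.build_profile_matrix(analysis.normalized_mean, design, analysis.results, 1)
        p2 = emb.build_profile_matrix(analysis.normalized_mean, design, analysis.results, 2)
        assert set(p2.index) <= set(p1.index)

    def test_unreachable_threshold_errors(self, spiked_screen):
        design, _, _, analysis = spiked_screen
        with pytest.raises(ValueError, match="nothing to embed"):
            emb.build_profile_matrix(
                analysis.normalized_mean, design, analysis.results, 999
            )


class TestHierarchicalCluster:
    def test_identical_columns_merge_first_at_zero(self):
        vals = pd.DataFrame(
            {"e1": [1.0, 2.0], "e2": [1.0, 2.0], "e3": [9.0, 9.0]}
        )
        Z = emb.hierarchical_cluster(make_matrix(vals), zero_fill=True)
        assert Z[0, 2] == 0.0
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_zero_fill_places_empty_column_at_norm_distance(self):
        vals = pd.DataFrame({"e1": [3.0, 4.0], "e2": [np.nan, np.nan]})
        Z = emb.hierarchical_cluster(make_matrix(vals), zero_fill=True)
        assert Z[0, 2] == pytest.approx(5.0)

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(2)
        vals = pd.DataFrame(rng.normal(20, 3, size=(30, 8)))
        Z = emb.hierarchical_cluster(make_matrix(vals))
        heights = Z[:, 2]
        assert (np.diff(heights) >= -1e-12).all()

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            emb.hierarchical_cluster(make_matrix(pd.DataFrame({"e1": [1.0]})))
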