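"""Contact featurization, embedding, clustering and cluster summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swishx.clustermaps import (
    HOLO_LABEL,
    NOISE_LABEL,
    cluster_embedding,
    concat_features,
    featurize_frames,
    holo_density_contour,
    reduce_and_embed,
    select_pocket_residues,
    summarize_clusters,
    switching_value,
)
from swishx.synthetic import (
    SyntheticPocketSpec,
    generate_two_state_features,
    synthetic_pocket_definition,
    two_state_templates,
)


class TestResidueSelection:
    def test_inside_shell_selected(self):
        out = select_pocket_residues(np.array([[5.0, 0, 0]]), np.zeros(3))
        assert list(out) == [0]

    def test_boundary_strictly_inclusive(self):
        coms = np.array([[7.0, 0, 0], [7.01, 0, 0]])
        out = select_pocket_residues(coms, np.zeros(3))
        assert list(out) == [0]

    def test_three_residue_distances(self):
        coms = np.array([[3.0, 0, 0], [0, 6.9, 0], [0, 0, 12.0]])
        out = select_pocket_residues(coms, np.zeros(3), residue_ids=[11, 22, 33])
        assert list(out) == [11, 22]

    def test_empty_selection_suggests_larger_shell(self):
        with pytest.raises(ValueError, match="larger shell"):
            select_pocket_residues(np.array([[50.0, 0, 0]]), np.zeros(3))


class TestSwitching:
    def test_limits_and_reference_values(self):
        assert switching_value(0.0) == 1.0
        assert switching_value(0.4) == pytest.approx(0.941176, abs=1e-6)
        assert switching_value(1.0) == pytest.approx(0.290578, abs=1e-6)

    def test_removable_singularity_at_r0(self):
        assert switching_value(0.8) == pytest.approx(0.5, abs=1e-9)
        near = switching_value(0.8 + 1e-9)
        assert near == pytest.approx(0.5, abs=1e-6)

    @given(st.floats(0.01, 5.0), st.floats(0.011, 5.0))
    @settings(max_examples=60, deadline=None)
    def test_strictly_decreasing(self, r1, r2):
        if abs(r1 - r2) < 1e-9:
            return
        lo, hi = min(r1, r2), max(r1, r2)
        assert switching_value(lo) > switching_value(hi)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            switching_value(-0.1)


class TestFeaturize:
    def test_fixed_pair_at_r0_gives_half(self):
        coms = np.zeros((5, 2, 3))
        coms[:, 1, 0] = 8.0  # 8 A = 0.8 nm
        m = featurize_frames(coms)
        assert m.values.shape == (5, 1)
        assert np.allclose(m.values, 0.5)

    def test_identical_frames_identical_rows(self, rng):
        frame = rng.uniform(-5, 5, (6, 3))
        coms = np.repeat(frame[None], 4, axis=0)
        m = featurize_frames(coms)
        assert np.array_equal(m.values[0], m.values[3])

    def test_pair_count(self, rng):
        coms = rng.uniform(-5, 5, (3, 4, 3))
        m = featurize_frames(coms)
        assert m.values.shape[1] == 6  # C(4,2)

    def test_entries_bounded(self, rng):
        coms = rng.uniform(-20, 20, (10, 5, 3))
        m = featurize_frames(coms)
        assert np.all((m.values >= 0) & (m.values <= 1))

    def test_nonfinite_frame_named(self):
        coms = np.zeros((3, 2, 3))
        coms[1, 0, 0] = np.nan
        with pytest.raises(ValueError, match="frame 1"):
            featurize_frames(coms)

    def test_column_mismatch_between_runs(self, rng):
        a = featurize_frames(rng.uniform(0, 5, (3, 4, 3)))
        b = featurize_frames(rng.uniform(0, 5, (3, 5, 3)))
        with pytest.raises(ValueError, match="mismatch"):
            concat_features([a, b])


class TestReduceAndEmbed:
    def test_duplicate_frames_embed_nearby(self, rng):
        frame = rng.uniform(0, 8, (40, 6, 3))
        coms = np.concatenate([frame, frame[:1], frame[:1]], axis=0)
        feats = featurize_frames(coms)
        coords, _ = reduce_and_embed(feats, None, seed=0)
        span = np.linalg.norm(coords.max(axis=0) - coords.min(axis=0))
        d = np.linalg.norm(coords[-1] - coords[-2])
        assert d <= 1e-3 * span + 1e-9

    def test_rank_bounded_by_contacts(self, rng):
        # 5 residues -> 10 contacts: the linear stage keeps 10, not 50
        from sklearn.decomposition import PCA

        coms = rng.uniform(0, 8, (80, 5, 3))
        feats = featurize_frames(coms)
        rank = min(50, feats.values.shape[1], len(feats.values) - 1)
        assert rank == 10

    def test_planted_populations_separate(self):
        """Disjoint contact signatures embed into well-separated groups."""
        from sklearn.metrics import silhouette_score

        spec = SyntheticPocketSpec(n_frames=150, switch_frame=75, seed=3)
        bundle = generate_two_state_features(spec)
        feats = featurize_frames(bundle.coords)
        coords, _ = reduce_and_embed(feats, None, seed=3)
        assert silhouette_score(coords, bundle.labels) >= 0.5

    def test_pca_stage_is_variance_optimal(self, rng):
        """The linear stage captures at least the variance of any random
        equal-rank projection (optimality of the principal subspace)."""
        from sklearn.decomposition import PCA

        X = rng.standard_normal((60, 12)) @ rng.standard_normal((12, 12))
        Z = PCA(n_components=3).fit_transform(X)
        var_pca = Z.var(axis=0).sum()
        Xc = X - X.mean(axis=0)
        for _ in range(40):
            Q, _ = np.linalg.qr(rng.standard_normal((12, 3)))
            assert (Xc @ Q).var(axis=0).sum() <= var_pca + 1e-9


class TestClustering:
    def test_two_planted_blobs_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        a = rng.normal([0, 0], 0.5, (500, 2))
        b = rng.normal([10, 10], 0.5, (500, 2))
        coords = np.concatenate([a, b])
        truth = np.repeat([0, 1], 500)
        cmap = cluster_embedding(coords, min_cluster_size=75)
        assert cmap.n_clusters == 2
        member = cmap.labels >= 0
        assert adjusted_rand_score(truth[member], cmap.labels[member]) >= 0.9

    def test_uniform_noise_yields_no_clusters(self, rng):
        coords = rng.uniform(0, 1, (1000, 2))
        cmap = cluster_embedding(coords, min_cluster_size=200)
        assert cmap.n_clusters == 0

    def test_holo_points_never_clustered(self, rng):
        coords = rng.normal(0, 0.3, (300, 2))
        holo = np.ones(300, dtype=bool)
        cmap = cluster_embedding(coords, holo, min_cluster_size=50)
        assert np.all(cmap.labels == HOLO_LABEL)
        assert cmap.n_clusters == 0

    def test_frame_order_permutation_stable(self, rng):
        a = rng.normal([0, 0], 0.4, (300, 2))
        b = rng.normal([8, 8], 0.4, (300, 2))
        coords = np.concatenate([a, b])
        cm1 = cluster_embedding(coords, min_cluster_size=75)
        perm = rng.permutation(len(coords))
        cm2 = cluster_embedding(coords[perm], min_cluster_size=75)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(cm1.labels[perm], cm2.labels) == pytest.approx(1.0)


class TestContours:
    def test_isotropic_cloud_roughly_circular(self, rng):
        coords = rng.normal(0, 1.0, (10_000, 2))
        holo = np.ones(len(coords), dtype=bool)
        conts = holo_density_contour(coords, holo, levels=[0.5])
        lines = conts[0]["polylines"]
        assert lines
        longest = max(lines, key=len)
        spans = longest.max(axis=0) - longest.min(axis=0)
        ratio = spans[0] / spans[1]
        assert 0.8 <= ratio <= 1.25

    def test_peak_level_degenerate(self, rng):
        coords = rng.normal(0, 1.0, (500, 2))
        conts = holo_density_contour(coords, np.ones(500, bool), levels=[1.0])
        assert conts[0]["polylines"] == []

    def test_too_few_points_rejected(self, rng):
        coords = rng.normal(0, 1, (5, 2))
        with pytest.raises(ValueError, match="10 holo points"):
            holo_density_contour(coords, np.ones(5, bool))

    def test_identical_points_rejected(self):
        coords = np.zeros((20, 2))
        with pytest.raises(ValueError, match="degenerate"):
            holo_density_contour(coords, np.ones(20, bool))


class TestSummaries:
    def _map(self, rng, sizes=(30, 20)):
        coords, labels = [], []
        for cid, (n, c) in enumerate(zip(sizes, ((0, 0), (10, 10)))):
            coords.append(rng.normal(c, 0.3, (n, 2)))
            labels += [cid] * n
        coords = np.concatenate(coords)
        from swishx.clustermaps import ClusterMap

        return ClusterMap(
            coords=coords,
            labels=np.array(labels),
            holo_mask=np.zeros(len(coords), bool),
            min_cluster_size=5,
        )

    def test_median_exposure_per_cluster(self, rng):
        cmap = self._map(rng)
        exposure = np.array([10.0, 90.0, 50.0] * 10 + [5.0] * 20)
        rmsd = np.ones(50)
        out = summarize_clusters(cmap, exposure, rmsd, k=10)
        assert out[0].median_exposure == 50.0
        assert out[1].median_exposure == 5.0

    def test_small_cluster_clamped_with_warning(self, rng):
        cmap = self._map(rng, sizes=(30, 4))
        out = summarize_clusters(cmap, np.zeros(34), np.zeros(34), k=10)
        small = [s for s in out if s.size == 4][0]
        assert len(small.representative_frames) == 4
        assert "only 4" in small.warning

    def test_open_cluster_has_higher_exposure_on_synthetic_set(self):
        """End-to-end: planted open cluster outranks the closed one."""
        from swishx.pocket import exposure_series

        spec = SyntheticPocketSpec(n_frames=300, switch_frame=150, seed=9)
        bundle = generate_two_state_features(spec)
        feats = featurize_frames(bundle.coords)
        coords, holo = reduce_and_embed(feats, None, seed=9)
        cmap = cluster_embedding(coords, holo, min_cluster_size=75)
        assert cmap.n_clusters >= 2
        pocket = synthetic_pocket_definition(spec)
        series = exposure_series(
            bundle.coords, np.arange(len(bundle.coords), dtype=float),
            pocket.atom_radii, pocket, align=False,
        )
        out = summarize_clusters(
            cmap, series["exposure"].to_numpy(), series["rmsd"].to_numpy()
        )
        med = {s.cluster_id: s.median_exposure for s in out}
        frac_open = {
            s.cluster_id: np.mean(bundle.labels[cmap.labels == s.cluster_id])
            for s in out
        }
        open_id = max(frac_open, key=frac_open.get)
        closed_id = min(frac_open, key=frac_open.get)
        assert med[open_id] > med[closed_id]
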