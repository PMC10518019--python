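"""Dot detection, intensity features and K-means triage."""

import numpy as np
import pandas as pd
import pytest

from scmst import spotcall
from scmst.utils import add_blob, gaussian_kernel_3d

SIGMA = (1.0, 1.3, 1.3)


def plant_dots(shape, positions, amplitudes, background=0.0, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    vol = np.full(shape, background, float)
    kernel = gaussian_kernel_3d(SIGMA)
    for p, a in zip(positions, amplitudes):
        add_blob(vol, p, kernel, a)
    if noise_sd:
        vol += rng.normal(0, noise_sd, shape)
    return vol


class TestDetect:
    def test_pure_noise_yields_few_weak_dots(self):
        rng = np.random.default_rng(0)
        vol = rng.normal(100, 2, (10, 64, 64))
        dots = spotcall.detect_dots(vol, floor_quantile=0.999)
        assert len(dots) < 30
        if len(dots):
            feats = spotcall.dot_features(vol, dots)
            # no detection looks like real signal (SNR > 3 over the baseline)
            assert (feats["mean_intensity"] < 100 + 3 * 2).all()

    def test_isolated_dots_found_at_planted_positions(self):
        positions = [(5, 10, 10), (5, 30, 40), (3, 50, 20), (7, 20, 55)]
        vol = plant_dots((10, 64, 64), positions, [500] * 4,
                         background=100, noise_sd=2)
        dots = spotcall.detect_dots(vol, floor_quantile=0.999)
        det = dots[["z", "y", "x"]].to_numpy()
        assert len(det) == 4
        for p in positions:
            assert (np.abs(det - p).max(axis=1) <= 1).any()

    def test_two_merged_dots_one_detection(self):
        vol = plant_dots((10, 64, 64), [(5, 30, 30), (5, 30, 31)], [500, 480],
                         background=100, noise_sd=2)
        dots = spotcall.detect_dots(vol, floor_quantile=0.999)
        assert len(dots) == 1

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            spotcall.detect_dots(np.zeros((4, 8, 8)), psf_sigma=(0, 1, 1))


class TestFeatures:
    def test_three_voxel_support_arithmetic(self):
        # sigma (0.5, 1.0, 0.5): support = centre voxel plus its two y-neighbours
        vol = np.zeros((5, 5, 5))
        vol[2, 1, 2], vol[2, 2, 2], vol[2, 3, 2] = 10.0, 20.0, 30.0
        dots = pd.DataFrame({"z": [2], "y": [2], "x": [2]})
        feats = spotcall.dot_features(vol, dots, psf_sigma=(0.5, 1.0, 0.5))
        assert feats["mean_intensity"].iloc[0] == pytest.approx(20.0)
        expected_sd = np.std([10.0, 20.0, 30.0])  # population sd
        assert feats["intensity_variability"].iloc[0] == pytest.approx(expected_sd)

    def test_uniform_dot_zero_variability(self):
        vol = np.full((5, 5, 5), 7.0)
        dots = pd.DataFrame({"z": [2], "y": [2], "x": [2]})
        feats = spotcall.dot_features(vol, dots, psf_sigma=SIGMA)
        assert feats["intensity_variability"].iloc[0] == 0.0

    def test_features_invariant_to_dot_order(self):
        vol = plant_dots((8, 32, 32), [(4, 10, 10), (4, 20, 20)], [300, 600])
        dots = pd.DataFrame({"z": [4, 4], "y": [10, 20], "x": [10, 20]})
        fwd = spotcall.dot_features(vol, dots)
        rev = spotcall.dot_features(vol, dots.iloc[::-1].reset_index(drop=True))
        assert np.allclose(
            np.sort(fwd["mean_intensity"]), np.sort(rev["mean_intensity"]))


def gaussian_blob_features(centers, n_per, spread, seed):
    rng = np.random.default_rng(seed)
    rows = []
    for (mi, vi) in centers:
        rows.append(np.column_stack([
            rng.normal(mi, spread, n_per), rng.normal(vi, spread / 4, n_per)]))
    x = np.vstack(rows)
    return pd.DataFrame(x, columns=["mean_intensity", "intensity_variability"])


class TestSelectK:
    def test_two_separated_blobs(self):
        feats = gaussian_blob_features([(100, 10), (1000, 100)], 60, 30, seed=1)
        k, diag = spotcall.select_k(feats, seed=0)
        assert k == 2

    def test_three_separated_blobs(self):
        feats = gaussian_blob_features([(100, 10), (1000, 100), (4000, 400)],
                                       60, 30, seed=2)
        k, diag = spotcall.select_k(feats, seed=0)
        assert k == 3
        assert diag["elbow_k"] in diag["sse"] or diag["elbow_k"] is None

    def test_degenerate_identical_features(self):
        feats = pd.DataFrame({"mean_intensity": [5.0] * 20,
                              "intensity_variability": [1.0] * 20})
        k, diag = spotcall.select_k(feats)
        assert k == 1
        assert diag["warnings"]


class TestTriage:
    def three_class_features(self, seed=0, n_true=200, n_ns=60, n_art=15):
        # classes separated by far more than 4 sd, like the phantom defaults
        return pd.concat([
            gaussian_blob_features([(300, 40)], n_ns, 50, seed=seed),
            gaussian_blob_features([(1000, 130)], n_true, 70, seed=seed + 1),
            gaussian_blob_features([(3500, 450)], n_art, 200, seed=seed + 2),
        ], ignore_index=True)

    def test_middle_band_keeps_true_class(self):
        feats = self.three_class_features()
        truth = np.array(["ns"] * 60 + ["true"] * 200 + ["art"] * 15)
        res, kept = spotcall.kmeans_triage(feats, 3, seed=0)
        assert set(res.retained) <= set(range(3))
        assert len(res.retained) < 3  # at least one cluster rejected
        recall = kept[truth == "true"].mean()
        precision = (truth[kept] == "true").mean()
        assert recall >= 0.95
        assert precision >= 0.95

    def test_only_true_dots_forced_k2_keeps_brighter_half(self):
        feats = gaussian_blob_features([(1000, 130)], 150, 70, seed=3)
        res, kept = spotcall.kmeans_triage(feats, 2, seed=0)
        rejected = feats[~kept]["mean_intensity"]
        assert rejected.mean() < feats[kept]["mean_intensity"].mean()
        assert kept.mean() >= 0.5

    def test_k1_keeps_everything_with_warning(self):
        feats = gaussian_blob_features([(1000, 130)], 10, 50, seed=4)
        res, kept = spotcall.kmeans_triage(feats, 1, seed=0)
        assert kept.all()
        assert res.warnings

    def test_determinism_under_seed(self):
        feats = self.three_class_features(seed=5)
        _, kept_a = spotcall.kmeans_triage(feats, 3, seed=7)
        _, kept_b = spotcall.kmeans_triage(feats, 3, seed=7)
        assert np.array_equal(kept_a, kept_b)

    def test_kept_mask_independent_of_input_order(self):
        feats = self.three_class_features(seed=6)
        perm = np.random.default_rng(0).permutation(len(feats))
        _, kept = spotcall.kmeans_triage(feats, 3, seed=1)
        _, kept_p = spotcall.kmeans_triage(
            feats.iloc[perm].reset_index(drop=True), 3, seed=1)
        assert np.array_equal(kept[perm], kept_p)

    def test_raising_artifact_quantile_grows_kept_set(self):
        feats = self.three_class_features(seed=7)
        _, kept_low = spotcall.kmeans_triage(feats, 3, seed=1,
                                             artifact_quantile=0.5)
        _, kept_high = spotcall.kmeans_triage(feats, 3, seed=1,
                                              artifact_quantile=0.9999)
        assert set(np.flatnonzero(kept_low)) <= set(np.flatnonzero(kept_high))

    def test_rejected_cluster_never_leaks(self):
        feats = self.three_class_features(seed=8)
        res, kept = spotcall.kmeans_triage(feats, 3, seed=2)
        labels = res.diagnostics["labels"]
        assert not np.any(kept & ~np.isin(labels, res.retained))


class TestRecovery:
    def _dots(self, genes, kept=True):
        return pd.DataFrame({"gene": genes, "kept": kept})

    def test_identical_sets_full_recovery(self):
        d = self._dots(["a"] * 10 + ["b"] * 5)
        out = spotcall.recovery_rate(d, d)
        assert out["overall"] == 1.0
        assert out["passed"]

    def test_half_removed_fails_default_threshold(self):
        init = self._dots(["a"] * 10)
        rep = self._dots(["a"] * 5)
        out = spotcall.recovery_rate(init, rep)
        assert out["overall"] == 0.5
        assert not out["passed"]

    def test_zero_initial_gene_reported_missing(self):
        init = self._dots(["a"] * 4)
        rep = self._dots(["a"] * 3 + ["b"] * 2)
        out = spotcall.recovery_rate(init, rep)
        row = out["per_gene"].set_index("gene").loc["b"]
        assert np.isnan(row["recovery"])
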