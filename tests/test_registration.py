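"""Anchor rotation, affine CPD, nearest-neighbor mapping, label transfer."""

import numpy as np
import pytest

from ciona_visuomotor.centroid_io import CentroidDataset
from ciona_visuomotor.registration import (
    ConfigurationError,
    DegenerateGeometryError,
    anchor_rotation,
    cpd_affine_register,
    map_nearest,
    register_dataset,
)
from ciona_visuomotor.synthetic_data import CloudConfig, perturb_dataset


def rotz(deg):
    a = np.deg2rad(deg)
    return np.array([[np.cos(a), -np.sin(a), 0],
                     [np.sin(a), np.cos(a), 0],
                     [0, 0, 1.0]])


def planar_dataset(dataset_id="d", transform=None):
    pts = np.array([[10.0, 0, 0], [14, 3, 0], [18, -2, 0], [12, 5, 0],
                    [16, 1, 0.0]])
    anchors = {"antenna_L": np.array([0.0, 0, 0])}
    if transform is not None:
        pts = pts @ transform.T
        anchors = {k: transform @ v for k, v in anchors.items()}
    return CentroidDataset(dataset_id, [f"c{i}" for i in range(len(pts))],
                           pts, anchors=anchors)


class TestAnchorRotation:
    def test_identity_when_source_equals_reference(self):
        d = planar_dataset()
        init = anchor_rotation(d, d)
        np.testing.assert_allclose(init.R, np.eye(3), atol=1e-12)

    def test_recovers_known_z_rotation(self):
        ref = planar_dataset("ref")
        src = planar_dataset("src", transform=rotz(90))
        init = anchor_rotation(src, ref)
        # applying R to the rotated source vector re-aligns it with the
        # reference's anchor->centroid vector
        v_src = src.positions.mean(0) - src.anchors["antenna_L"]
        v_ref = ref.positions.mean(0) - ref.anchors["antenna_L"]
        out = init.R @ v_src
        angle = np.arccos(np.clip(
            out @ v_ref / np.linalg.norm(out) / np.linalg.norm(v_ref), -1, 1))
        assert angle < 1e-6
        np.testing.assert_allclose(init.R, rotz(-90), atol=1e-9)

    def test_multi_anchor_procrustes(self, ocellus_reference):
        ref, _ = ocellus_reference
        R_true = rotz(40)
        src = ref.copy()
        src.positions = src.positions @ R_true.T
        src.anchors = {k: R_true @ v for k, v in src.anchors.items()}
        init = anchor_rotation(src, ref)
        np.testing.assert_allclose(init.R, R_true.T, atol=1e-9)

    def test_no_shared_anchor_is_configuration_error(self):
        ref = planar_dataset("ref")
        src = planar_dataset("src")
        src.anchors = {"ddN_R": np.zeros(3)}
        with pytest.raises(ConfigurationError, match="anchor"):
            anchor_rotation(src, ref)

    def test_anchor_at_cluster_centroid_is_degenerate(self):
        d = planar_dataset()
        d.anchors = {"antenna_L": d.positions.mean(axis=0)}
        with pytest.raises(DegenerateGeometryError):
            anchor_rotation(d, planar_dataset("ref"))


class TestAffineCPD:
    def test_identity_on_equal_clouds(self, rng):
        pts = rng.uniform(-30, 30, size=(20, 3))
        tf, s2, nll, n_iter, conv = cpd_affine_register(pts, pts)
        np.testing.assert_allclose(tf.B, np.eye(3), atol=1e-6)
        np.testing.assert_allclose(tf.t, np.zeros(3), atol=1e-6)
        assert conv and n_iter <= 20

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_known_affine_exactly(self, seed):
        """Noiseless affine recovery, cross-checked against the closed-form
        least-squares fit on the known correspondence."""
        rng = np.random.default_rng(seed)
        Y = rng.uniform(-25, 25, size=(30, 3))
        A = rotz(25) @ (np.eye(3) + rng.uniform(-0.2, 0.2, (3, 3))
                        * (1 - np.eye(3)))
        b = rng.uniform(-20, 20, 3)
        X = Y @ A.T + b
        tf, *_rest, conv = cpd_affine_register(Y, X, max_iterations=1000,
                                               tolerance=1e-3)
        assert conv
        rmsd = np.sqrt(np.mean(np.sum((tf.apply(Y) - X) ** 2, axis=1)))
        assert rmsd <= 1e-3
        # independent oracle: least squares with known correspondence
        H = np.hstack([Y, np.ones((len(Y), 1))])
        coef, *_ = np.linalg.lstsq(H, X, rcond=None)
        np.testing.assert_allclose(tf.B, coef[:3].T, atol=1e-6)
        np.testing.assert_allclose(tf.t, coef[3], atol=1e-5)

    def test_nll_non_increasing_and_sigma2_positive(self, rng):
        Y = rng.uniform(-25, 25, size=(30, 3))
        X = Y + rng.normal(0, 0.5, size=Y.shape)
        tf, s2, nll, n_iter, conv = cpd_affine_register(Y, X)
        assert conv and n_iter <= 1000
        assert all(v > 0 for v in s2)
        diffs = np.diff(nll)
        assert np.all(diffs <= 1e-8)

    def test_sigma2_tracks_residuals(self, rng):
        """Final sigma^2 within an order of magnitude of the mean squared
        residual on converged noisy runs."""
        Y = rng.uniform(-25, 25, size=(30, 3))
        X = Y + rng.normal(0, 0.5, size=Y.shape)
        tf, s2, *_ = cpd_affine_register(Y, X)
        msd = np.mean(np.sum((tf.apply(Y) - X) ** 2, axis=1))
        assert msd / 10 <= s2[-1] <= msd * 10

    def test_jittered_cloud_converges_with_small_residuals(self):
        """Monte-Carlo: 0.5 um jitter -> mean residual within 3x jitter."""
        means = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            Y = rng.uniform(-25, 25, size=(30, 3))
            X = Y + rng.normal(0, 0.5, size=Y.shape)
            tf, s2, nll, n_iter, conv = cpd_affine_register(Y, X)
            assert conv and n_iter <= 1000
            resid = np.linalg.norm(tf.apply(Y) - X, axis=1)
            means.append(resid.mean())
        assert np.mean(means) <= 3 * 0.5

    def test_degenerate_inputs_rejected(self, rng):
        flat = np.c_[rng.uniform(-10, 10, (10, 2)), np.zeros(10)]
        with pytest.raises(DegenerateGeometryError, match="coplanar"):
            cpd_affine_register(flat, flat + 0.1)
        with pytest.raises(ValueError, match="finite"):
            cpd_affine_register(np.full((5, 3), np.nan), rng.uniform(size=(5, 3)))
        with pytest.raises(DegenerateGeometryError):
            cpd_affine_register(rng.uniform(size=(3, 3)), rng.uniform(size=(5, 3)))


class TestMapNearest:
    def test_tie_breaks_to_lexicographically_smaller_id(self):
        src = np.array([[0.0, 0, 0]])
        ref = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        corr, dist = map_nearest(src, ["s"], ref, ["B", "A"])
        assert corr["s"] == "A"
        assert dist["s"] == pytest.approx(1.0)

    def test_identity_mapping_on_equal_clouds(self, rng):
        pts = rng.uniform(-10, 10, size=(8, 3))
        ids = [f"c{i}" for i in range(8)]
        corr, dist = map_nearest(pts, ids, pts, ids)
        assert corr == {i: i for i in ids}
        assert all(d == 0 for d in dist.values())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        src = rng.uniform(-5, 5, size=(2, 3))
        ref = rng.uniform(-5, 5, size=(3, 3))
        sids = ["s0", "s1"]
        rids = ["r0", "r1", "r2"]
        corr, _ = map_nearest(src, sids, ref, rids)
        for i, s in enumerate(sids):
            d = [np.linalg.norm(src[i] - ref[j]) for j in range(3)]
            assert corr[s] == rids[int(np.argmin(d))]

    def test_one_to_one_assignment_is_a_bijection(self, rng):
        src = rng.uniform(-10, 10, size=(5, 3))
        ref = rng.uniform(-10, 10, size=(7, 3))
        corr, _ = map_nearest(src, [f"s{i}" for i in range(5)],
                              ref, [f"r{i}" for i in range(7)], one_to_one=True)
        assert len(set(corr.values())) == len(corr)


class TestRegisterDataset:
    def test_self_registration_is_identity(self, ocellus_reference, circuit,
                                           ocellus_params):
        ref, label_map = ocellus_reference
        a = register_dataset(ref, circuit, ocellus_params)
        assert a.registration.correspondence == {c: c for c in ref.cell_ids}
        for cid in ref.cell_ids:
            assert a.labels[cid] == label_map[cid]

    def test_random_pose_label_transfer(self, ocellus_reference, circuit,
                                        ocellus_params):
        """Random affine pose + 0.5 um jitter: >= 90% correct over 20 seeds."""
        ref, _ = ocellus_reference
        cfg = CloudConfig(region="ocellus", jitter_um=0.5)
        accs = []
        for seed in range(20):
            ds, _ = perturb_dataset(ref, cfg, np.random.default_rng(seed))
            a = register_dataset(ds, circuit, ocellus_params)
            corr = a.registration.correspondence
            accs.append(np.mean([corr[c] == c for c in ds.cell_ids]))
        assert np.mean(accs) >= 0.90

    def test_missing_anchors_is_configuration_error(self, circuit,
                                                    ocellus_reference,
                                                    ocellus_params):
        ref, _ = ocellus_reference
        bare = ref.copy()
        bare.anchors = {}
        with pytest.raises(ConfigurationError, match="anchor"):
            register_dataset(bare, circuit, ocellus_params)

    def test_equivariance_to_pre_rotation(self, ocellus_reference, circuit,
                                          ocellus_params):
        """Rotating the source (anchors included) does not change the final
        correspondence: the anchor init absorbs pose."""
        ref, _ = ocellus_reference
        ds, _ = perturb_dataset(ref, CloudConfig(region="ocellus",
                                                 jitter_um=0.3),
                                np.random.default_rng(7))
        base = register_dataset(ds, circuit, ocellus_params)
        R = rotz(65)
        rot = ds.copy()
        rot.positions = ds.positions @ R.T
        rot.anchors = {k: R @ v for k, v in ds.anchors.items()}
        rotated = register_dataset(rot, circuit, ocellus_params)
        assert rotated.registration.correspondence == \
            base.registration.correspondence

    def test_multiplicity_and_no_call_bookkeeping(self, ocellus_reference,
                                                  circuit, ocellus_params):
        ref, _ = ocellus_reference
        ds, _ = perturb_dataset(ref, CloudConfig(region="ocellus",
                                                 dropout=0.3),
                                np.random.default_rng(3))
        a = register_dataset(ds, circuit, ocellus_params)
        assert sum(a.multiplicity.values()) == len(ds.cell_ids)
        assert set(a.no_call_ids()) == set(a.reference_ids) - set(a.labels)
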