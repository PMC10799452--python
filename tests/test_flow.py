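"""Flow-field machinery: targets, 3D averaging, tracking, network, training."""

import copy

import numpy as np
import pytest

from pomecell.evaluation import aji
from pomecell.flow.net import (FlowPredictor, RAdam, TrainConfig, UNet,
                               build_network, flow_loss, load_model,
                               normalize_image, save_model, train,
                               _transform_pair)
from pomecell.flow.predict import FlowField3D, predict_volume
from pomecell.flow.targets import flows3d_from_labels, labels_to_flows
from pomecell.flow.tracking import mask_and_cluster


def disk_labels(h=33, w=33, centers=((16, 16),), radius=10):
    yy, xx = np.mgrid[:h, :w]
    lab = np.zeros((h, w), int)
    for i, (cy, cx) in enumerate(centers, start=1):
        lab[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = i
    return lab


class TestFlowTargets:
    def test_background_is_zero(self):
        target = labels_to_flows(disk_labels())
        bg = disk_labels() == 0
        assert not target[:, bg].any()

    def test_empty_slice_all_zero(self):
        assert not labels_to_flows(np.zeros((16, 16), int)).any()

    def test_disk_gradients_point_to_center(self):
        lab = disk_labels()
        target = labels_to_flows(lab)
        yy, xx = np.mgrid[:33, :33]
        dirs = np.stack([16.0 - yy, 16.0 - xx])
        norm = np.linalg.norm(dirs, axis=0)
        m = (lab > 0) & (norm > 1.5)
        cos = (target[0] * dirs[0] + target[1] * dirs[1])[m] / norm[m]
        assert cos.mean() >= 0.95

    def test_unit_length_inside_mask(self):
        lab = disk_labels(centers=((10, 10), (24, 22)), radius=7)
        target = labels_to_flows(lab)
        mag = np.hypot(target[0], target[1])[lab > 0]
        assert mag.max() <= 1.0 + 1e-5
        assert np.median(mag) > 0.9

    def test_two_disks_integrate_to_two_fixed_points(self):
        lab = disk_labels(centers=((10, 10), (24, 24)), radius=7)
        vol = np.stack([lab] * 8)  # prism: same labels in every XY slice
        field = flows3d_from_labels(vol)
        labels = mask_and_cluster(field, vol > 0, min_size=8)
        assert labels.max() == 2
        value, _ = aji(vol, labels)
        assert value > 0.9

    def test_rotation_equivariance_on_symmetric_disk(self):
        lab = disk_labels()  # odd size, centred: unique median centre
        base = labels_to_flows(lab)
        rot = labels_to_flows(np.rot90(lab).copy())
        gy, gx = -np.rot90(base[1]), np.rot90(base[0])
        m = rot[2] > 0.5
        m[16, 16] = False  # the source pixel's direction is arbitrary
        assert np.abs(rot[0] - gy)[m].max() < 1e-5
        assert np.abs(rot[1] - gx)[m].max() < 1e-5


class TestAugmentation:
    def test_vectors_stay_unit_and_roi_binary(self):
        rng = np.random.default_rng(0)
        lab = disk_labels(centers=((10, 12), (22, 20)), radius=7)
        target = labels_to_flows(lab)
        img = rng.random(lab.shape).astype(np.float32)
        for _ in range(10):
            _, t2 = _transform_pair(img, target, rng)
            mag = np.hypot(t2[0], t2[1])[t2[2] > 0.5]
            assert mag.max() <= 1.0 + 1e-4
            assert set(np.unique(t2[2])) <= {0.0, 1.0}

    def test_flip_transform_matches_recomputed_flows(self):
        lab = disk_labels()
        base = labels_to_flows(lab)
        flipped = labels_to_flows(lab[::-1].copy())
        m = lab > 0
        m[16, 16] = False  # source pixel: arbitrary direction
        assert np.allclose(flipped[0][m], -base[0][::-1][m], atol=1e-5)
        assert np.allclose(flipped[1][m], base[1][::-1][m], atol=1e-5)


class TestPredictVolume:
    def test_constant_roi_averages_to_itself(self):
        def constant(img, orientation, index):
            out = np.zeros((3, *img.shape), np.float32)
            out[2] = 0.6
            return out

        field = predict_volume(constant, np.zeros((6, 7, 8), np.float32))
        assert np.allclose(field.roi, 0.6, atol=1e-6)

    def test_each_component_is_mean_of_two_orientations(self):
        # predictor marks each orientation with a distinct constant; the
        # recombined component must be the mean of the two stacks seeing it
        values = {"XY": (1.0, 2.0), "XZ": (3.0, 4.0), "YZ": (5.0, 6.0)}

        def marked(img, orientation, index):
            out = np.zeros((3, *img.shape), np.float32)
            out[0] = values[orientation][0]
            out[1] = values[orientation][1]
            return out

        field = predict_volume(marked, np.zeros((4, 4, 4), np.float32))
        assert np.allclose(field.vectors[0], (3.0 + 5.0) / 2)  # Z: XZ+YZ
        assert np.allclose(field.vectors[1], (1.0 + 6.0) / 2)  # Y: XY+YZ
        assert np.allclose(field.vectors[2], (2.0 + 4.0) / 2)  # X: XY+XZ

    def test_oracle_model_reproduces_reference_field(self, apple_phantom):
        labels = apple_phantom.cell_labels[:16, :16, :16]
        ref = flows3d_from_labels(labels)

        def oracle(img, orientation, index):
            if orientation == "XY":
                sl = labels[index]
            elif orientation == "XZ":
                sl = labels[:, index, :]
            else:
                sl = labels[:, :, index]
            return labels_to_flows(sl)

        again = predict_volume(oracle, np.zeros(labels.shape, np.float32))
        assert np.abs(again.vectors - ref.vectors).max() < 1e-6
        assert np.abs(again.roi - ref.roi).max() < 1e-6


class TestTracking:
    def test_all_zero_roi_gives_empty_labeling(self):
        field = FlowField3D(vectors=np.zeros((3, 8, 8, 8), np.float32),
                            roi=np.zeros((8, 8, 8), np.float32))
        labels = mask_and_cluster(field, np.ones((8, 8, 8), bool))
        assert labels.max() == 0

    def test_zero_vectors_reduce_to_connected_components(self):
        roi = np.zeros((10, 10, 10), np.float32)
        roi[1:4, 1:4, 1:4] = 1.0
        roi[6:9, 6:9, 6:9] = 1.0
        field = FlowField3D(vectors=np.zeros((3, 10, 10, 10), np.float32), roi=roi)
        labels = mask_and_cluster(field, np.ones((10, 10, 10), bool), min_size=4)
        assert labels.max() == 2

    def test_nan_field_raises(self):
        vec = np.zeros((3, 6, 6, 6), np.float32)
        vec[0, 0, 0, 0] = np.nan
        field = FlowField3D(vectors=vec, roi=np.ones((6, 6, 6), np.float32))
        with pytest.raises(ValueError):
            mask_and_cluster(field, np.ones((6, 6, 6), bool))

    @pytest.mark.parametrize("style", ["apple", "pear"])
    def test_representation_round_trip_both_styles(self, style, apple_phantom,
                                                   pear_phantom):
        """labels -> slice flows -> 3D average -> tracking: AJI >= 0.95."""
        ph = apple_phantom if style == "apple" else pear_phantom
        field = flows3d_from_labels(ph.cell_labels)
        labels = mask_and_cluster(field, ph.masks.cell_matrix, min_size=8)
        value, _ = aji(ph.cell_labels, labels)
        assert value >= 0.95


class TestNetwork:
    def test_parameter_count_deterministic(self):
        cfg = TrainConfig(base_feature_maps=8, depth=3, seed=4, epochs=1)
        assert build_network(cfg).n_parameters == build_network(cfg).n_parameters

    def test_output_shape_matches_input_with_three_channels(self):
        net = UNet(nbase=4, depth=3)
        y = net.forward(np.zeros((2, 1, 44, 52), np.float32))
        assert y.shape == (2, 3, 44, 52)

    def test_halving_features_reduces_parameters(self):
        big = UNet(nbase=16, depth=3)
        small = UNet(nbase=8, depth=3)
        assert small.n_parameters < big.n_parameters

    def test_gradients_match_finite_differences(self):
        net = UNet(nbase=4, depth=2, seed=1)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1, 12, 12)).astype(np.float32)
        t = rng.random((2, 3, 12, 12)).astype(np.float32)
        t[:, 2] = t[:, 2] > 0.5
        pred = net.forward(x)
        _, dpred = flow_loss(pred, t)
        net.backward(dpred)
        for name in ("enc0a_w", "dec1b_w", "head_w"):
            p, g = net.params[name], net.grads[name]
            idx = tuple(np.unravel_index(np.argmax(np.abs(g)), g.shape))
            eps, orig = 1e-2, p[idx]
            p[idx] = orig + eps
            lp, _ = flow_loss(net.forward(x), t)
            p[idx] = orig - eps
            lm, _ = flow_loss(net.forward(x), t)
            p[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=5e-2)

    def test_save_load_round_trip(self, tmp_path):
        cfg = TrainConfig(base_feature_maps=4, depth=2, seed=2, epochs=1)
        net = build_network(cfg)
        save_model(net, cfg, tmp_path / "m")
        loaded, cfg2 = load_model(tmp_path / "m")
        x = np.random.default_rng(1).random((1, 1, 16, 16)).astype(np.float32)
        assert np.allclose(net.forward(x), loaded.forward(x))
        assert cfg2 == cfg


class TestTraining:
    def _toy_pairs(self, n=8, size=24, seed=0):
        rng = np.random.default_rng(seed)
        pairs = []
        for _ in range(n):
            lab = disk_labels(size, size,
                              centers=((size // 2 + rng.integers(-3, 4),
                                        size // 2 + rng.integers(-3, 4)),),
                              radius=6)
            img = np.where(lab > 0, 150.0, 30.0) + rng.normal(0, 5, lab.shape)
            pairs.append((img.astype(np.float32), labels_to_flows(lab)))
        return pairs

    def test_recorded_loss_matches_independent_recomputation(self):
        """1 epoch over one batch of identical slices: logged loss equals
        5 x L2 + CE recomputed with the pre-update weights to 1e-5."""
        pairs = self._toy_pairs(1) * 8
        cfg = TrainConfig(epochs=1, batch_size=8, base_feature_maps=4, depth=2,
                          seed=3, augment=False, lr_decay_epoch=10)
        model = build_network(cfg)
        frozen = copy.deepcopy(model.params)
        log = train(model, pairs, cfg)
        oracle = UNet(nbase=4, depth=2, seed=3)
        oracle.params = frozen
        img, tgt = pairs[0]
        x = np.stack([normalize_image(img)] * 8)[:, None]
        t = np.stack([tgt] * 8)
        expected = (5.0 * float(np.mean((oracle.forward(x)[:, :2] - t[:, :2]) ** 2))
                    + _bce(oracle.forward(x)[:, 2], t[:, 2]))
        assert log["train_loss"].iloc[0] == pytest.approx(expected, abs=1e-5)

    def test_zero_flow_weight_excludes_gradient_loss(self):
        pairs = self._toy_pairs(4)
        x = np.stack([normalize_image(p[0]) for p in pairs])[:, None]
        t = np.stack([p[1] for p in pairs])
        net = UNet(nbase=4, depth=2, seed=0)
        pred = net.forward(x)
        with_flow, _ = flow_loss(pred, t, flow_weight=5.0)
        without, _ = flow_loss(pred, t, flow_weight=0.0)
        assert without == pytest.approx(_bce(pred[:, 2], t[:, 2]), rel=1e-6)
        assert with_flow > without

    def test_training_reduces_loss_on_synthetic_set(self):
        """>= 50 slices, 30 epochs: final loss below the first epoch's."""
        pairs = self._toy_pairs(50, seed=1)
        cfg = TrainConfig(epochs=30, batch_size=8, base_feature_maps=4,
                          depth=2, seed=0, lr_decay_epoch=25)
        model = build_network(cfg)
        log = train(model, pairs, cfg)
        assert log["train_loss"].iloc[-1] < log["train_loss"].iloc[0]

    def test_empty_training_set_raises(self):
        cfg = TrainConfig(epochs=1, base_feature_maps=4, depth=2)
        with pytest.raises(ValueError):
            train(build_network(cfg), [], cfg)


def _bce(z, t):
    return float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))


class TestRAdam:
    def test_reduces_quadratic(self):
        params = {"w": np.array([5.0, -3.0])}
        opt = RAdam(params, lr=0.05)
        for _ in range(400):
            opt.step({"w": 2.0 * params["w"]})
        assert np.abs(params["w"]).max() < 0.3
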