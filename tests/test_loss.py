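"""Composite loss identities, weight-map components, and soft-label
equivalence."""

import numpy as np
import pytest

from neoseg.autodiff import Tensor
from neoseg.loss import (
    LossConfig,
    WeightMap,
    build_weight_map,
    class_weights_median_frequency,
    composite_loss,
    dice_term,
    gradient_weights,
    median_frequency_weights,
    one_hot,
    pve_weights,
)


class TestMedianFrequency:
    def test_balanced_classes_unit_weights(self):
        lab = np.array([[0, 0], [1, 1]])
        np.testing.assert_allclose(class_weights_median_frequency(lab, 2), [1.0, 1.0])

    def test_75_25_example(self):
        lab = np.array([0, 0, 0, 1])
        np.testing.assert_allclose(
            class_weights_median_frequency(lab, 2), [2 / 3, 2.0], atol=1e-12
        )

    def test_three_class_example(self):
        lab = np.repeat([0, 1, 2], [6, 3, 1])
        np.testing.assert_allclose(
            class_weights_median_frequency(lab, 3), [0.5, 1.0, 3.0], atol=1e-12
        )

    def test_absent_class_weight_zero(self):
        w = class_weights_median_frequency(np.array([0, 0, 2, 2]), 4)
        assert w[1] == 0.0 and w[3] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            class_weights_median_frequency(np.array([], dtype=int), 2)

    def test_broadcast_to_pixels(self):
        lab = np.array([[0, 1], [1, 1]])
        m = median_frequency_weights(lab, 2, class_weights=np.array([0.5, 2.0]))
        np.testing.assert_allclose(m, [[0.5, 2.0], [2.0, 2.0]])


class TestGradientWeights:
    def test_constant_map_zero(self):
        assert gradient_weights(np.full((5, 5), 3)).sum() == 0.0

    def test_vertical_boundary_band(self):
        lab = np.zeros((6, 6), dtype=int)
        lab[:, 3:] = 1
        g = gradient_weights(lab)
        # central differences: nonzero exactly in the two columns at the edge
        assert np.all(g[:, [2, 3]] > 0)
        assert np.all(g[:, [0, 1, 4, 5]] == 0)
        assert np.all(g >= 0)

    def test_matches_finite_difference_oracle(self, rng):
        lab = rng.integers(0, 3, size=(7, 7))
        g = gradient_weights(lab, scale=2.0)
        gr, gc = np.gradient(lab.astype(float))
        np.testing.assert_allclose(g, 2.0 * np.sqrt(gr ** 2 + gc ** 2))


class TestPveWeights:
    def test_no_cortex_all_zero(self):
        gm, wm = pve_weights(np.zeros((5, 5), dtype=int), (1,), (2,))
        assert gm.sum() == 0 and wm.sum() == 0

    def test_disk_band_matches_morphology_oracle(self):
        from scipy import ndimage

        yy, xx = np.mgrid[:25, :25]
        disk = (yy - 12) ** 2 + (xx - 12) ** 2 <= 100
        lab = disk.astype(int)  # cortex = 1
        gm, wm = pve_weights(lab, (1,), (2,), radius=2)
        selem = ndimage.generate_binary_structure(2, 1)
        eroded = ndimage.binary_erosion(disk, selem, iterations=2)
        dilated = ndimage.binary_dilation(disk, selem, iterations=2)
        assert gm.astype(bool).sum() == (disk & ~eroded).sum()
        assert wm.astype(bool).sum() == (dilated & ~disk).sum()

    def test_masks_binary_scaled(self):
        lab = np.zeros((8, 8), dtype=int)
        lab[3:6, 3:6] = 1
        gm, wm = pve_weights(lab, (1,), (2,), gm_scale=2.5, wm_sulci_scale=0.5)
        assert set(np.unique(gm)) <= {0.0, 2.5}
        assert set(np.unique(wm)) <= {0.0, 0.5}

    def test_bad_class_id_rejected(self):
        with pytest.raises(ValueError):
            pve_weights(np.zeros((3, 3), dtype=int), ("cortex",), (2,))


class TestWeightMap:
    def test_total_is_component_sum(self):
        lab = np.zeros((10, 10), dtype=int)
        lab[2:8, 2:8] = 1
        lab[4:6, 4:6] = 2
        wmap = build_weight_map(lab, 3, cortex_ids=(1,), wm_ids=(2,))
        np.testing.assert_allclose(
            wmap.omega_total,
            wmap.omega_medianfreq + wmap.omega_gradient + wmap.omega_gm + wmap.omega_wm_sulci,
        )
        assert np.all(wmap.omega_total >= 0)

    def test_negative_component_rejected(self):
        z = np.zeros((2, 2))
        with pytest.raises(ValueError):
            WeightMap(z - 1, z, z, z)


class TestCompositeLoss:
    def test_perfect_prediction_identity(self):
        """p = y exactly: logistic term 0, Dice term -(classes present)."""
        lab = np.array([[0, 1], [1, 2]])
        y = one_hot(lab, 4)  # class 3 absent
        loss = composite_loss(Tensor(y.copy()), y)
        assert float(loss.data) == pytest.approx(-3.0, abs=1e-9)

    def test_uniform_prediction_logistic_closed_form(self):
        lab = np.zeros((4, 5), dtype=int)
        lab[1] = 1
        y = one_hot(lab, 4)
        p = np.full_like(y, 0.25)
        total = float(composite_loss(Tensor(p), y).data)
        # subtract the Dice part to isolate the logistic term
        logistic = total - dice_term(p, y)
        assert logistic == pytest.approx(20 * np.log(4), rel=1e-9)

    def test_omega_scales_logistic_only(self, rng):
        lab = rng.integers(0, 3, size=(6, 6))
        y = one_hot(lab, 3)
        p = np.full_like(y, 1 / 3)
        om = np.ones((6, 6))
        l1 = float(composite_loss(Tensor(p), y, om).data)
        l2 = float(composite_loss(Tensor(p), y, 2 * om).data)
        d = dice_term(p, y)
        assert l2 - d == pytest.approx(2 * (l1 - d), rel=1e-9)

    def test_dice_term_bounds_and_logistic_sign(self, rng):
        for _ in range(5):
            lab = rng.integers(0, 4, size=(5, 5))
            y = one_hot(lab, 4)
            q = rng.uniform(0.05, 1.0, size=y.shape)
            p = q / q.sum(axis=0, keepdims=True)
            d = dice_term(p, y)
            assert -4.0 <= d <= 0.0
            total = float(composite_loss(Tensor(p), y).data)
            assert total - d >= 0.0  # logistic part nonnegative

    def test_monotone_towards_truth(self, rng):
        lab = rng.integers(0, 3, size=(8, 8))
        y = one_hot(lab, 3)
        uniform = np.full_like(y, 1 / 3)
        losses = []
        for t in np.linspace(0, 0.95, 8):
            p = (1 - t) * uniform + t * y
            p = np.clip(p, 1e-6, None)
            p /= p.sum(axis=0, keepdims=True)
            losses.append(float(composite_loss(Tensor(p), y).data))
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_soft_identity_equals_one_hot(self):
        from neoseg.augmentation import external_spatial_augment

        lab = np.zeros((8, 8), dtype=int)
        lab[2:6, 2:6] = 1
        img = lab.astype(float)
        _, soft = external_spatial_augment(
            img, lab, (0.0, (0.0, 0.0), (1.0, 1.0)), mode="soft", n_classes=2
        )
        y = one_hot(lab, 2)
        np.testing.assert_allclose(soft, y, atol=1e-12)
        p = np.full_like(y, 0.5)
        assert float(composite_loss(Tensor(p), soft).data) == pytest.approx(
            float(composite_loss(Tensor(p), y).data)
        )

    def test_balanced_reduction_scales_terms(self, rng):
        lab = rng.integers(0, 3, size=(2, 6, 6))
        y = np.stack([one_hot(l, 3) for l in lab])
        q = rng.uniform(0.1, 1, size=y.shape)
        p = q / q.sum(axis=1, keepdims=True)
        raw = float(composite_loss(Tensor(p), y).data)
        bal = float(composite_loss(Tensor(p), y, reduction="balanced").data)
        d = dice_term(p, y)
        logistic = raw - d
        assert bal == pytest.approx(logistic / (2 * 36) + d / 3, rel=1e-6)

    def test_gradient_direction_improves_loss(self, rng):
        """One explicit gradient-descent step on p decreases the loss."""
        lab = rng.integers(0, 3, size=(5, 5))
        y = one_hot(lab, 3)
        q = rng.uniform(0.2, 1.0, size=y.shape)
        p0 = q / q.sum(axis=0, keepdims=True)
        t = Tensor(p0, requires_grad=True)
        loss = composite_loss(t, y)
        loss.backward()
        p1 = np.clip(p0 - 0.01 * t.grad, 1e-6, None)
        p1 /= p1.sum(axis=0, keepdims=True)
        assert float(composite_loss(Tensor(p1), y).data) < float(loss.data)
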