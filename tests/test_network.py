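"""Architecture contracts: block structure, parameter-equal variants,
weight-copy equivalence, forward determinism."""

import numpy as np
import pytest

from neoseg.autodiff import Tensor
from neoseg.geometry import ResolutionSpec
from neoseg.latent import InternalAugParams
from neoseg.network import CDB, IDB, NetworkSpec, SegNet, build_network
import neoseg.autodiff as ad


def small_spec(variant, **kw):
    kw.setdefault("n_classes", 4)
    kw.setdefault("filters", 4)
    kw.setdefault("min_inner", 8)
    return NetworkSpec(variant=variant, **kw)


class TestMaxout:
    def test_idempotent_on_equal_inputs(self, rng):
        x = Tensor(rng.normal(size=(1, 2, 3, 3)))
        np.testing.assert_array_equal(ad.maximum(x, x).data, x.data)

    def test_elementwise_example(self):
        a = Tensor(np.array([1.0, -2.0]))
        b = Tensor(np.array([0.0, 5.0]))
        np.testing.assert_array_equal(ad.maximum(a, b).data, [1.0, 5.0])

    def test_commutative(self, rng):
        a = Tensor(rng.normal(size=(2, 3)))
        b = Tensor(rng.normal(size=(2, 3)))
        np.testing.assert_array_equal(ad.maximum(a, b).data, ad.maximum(b, a).data)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            ad.maximum(Tensor(np.zeros((2, 2))), Tensor(np.zeros((2, 3))))


class TestBlocks:
    def test_cdb_preserves_spatial_shape(self, rng):
        block = CDB(3, 5, rng)
        out = block(Tensor(rng.normal(size=(2, 3, 9, 11))), training=True)
        assert out.shape == (2, 5, 9, 11)

    def test_cdb_zero_weights_finite(self, rng):
        block = CDB(2, 3, rng)
        for conv in block.convs:
            conv.weight.data[:] = 0
            conv.bias.data[:] = 0
        out = block(Tensor(rng.normal(size=(1, 2, 6, 6))), training=True)
        assert np.all(np.isfinite(out.data))

    def test_idb_structural_order(self, rng):
        """The input block's first three operations are BN, Conv, BN."""
        assert IDB.ops == ("bn", "conv", "bn")
        assert CDB.ops == ("prelu", "conv", "bn")
        block = IDB(1, 4, rng)
        assert hasattr(block, "bn_in")
        assert len(block.convs) == 4 and len(block.bns) == 4

    def test_idb_normalizes_constant_raw_input(self, rng):
        # a constant raw-intensity input leaves the input BN as the
        # per-channel affine of zeros (i.e. exactly beta)
        block = IDB(1, 3, rng)
        block.bn_in.beta.data[:] = 0.25
        out = block.bn_in(Tensor(np.full((2, 1, 8, 8), 3.7)), training=True)
        np.testing.assert_allclose(out.data, 0.25, atol=1e-4)

    def test_four_conv_sub_layers_each(self, rng):
        assert len(CDB(2, 4, rng).convs) == 4
        assert len(IDB(2, 4, rng).convs) == 4


class TestBuild:
    def test_parameter_census_equal_across_variants(self):
        counts = {
            v: build_network(small_spec(v), seed=0).parameter_count()
            for v in ("pool", "scale", "affine")
        }
        assert len(set(counts.values())) == 1

    def test_parameter_names_equal_across_variants(self):
        names = {
            v: set(build_network(small_spec(v), seed=0).parameters())
            for v in ("pool", "scale", "affine")
        }
        assert names["pool"] == names["scale"] == names["affine"]

    def test_depth_five_plus_bottleneck(self):
        net = build_network(small_spec("affine"), seed=0)
        enc = [net.enc1, net.enc2, net.enc3, net.enc4, net.enc5]
        dec = [net.dec5, net.dec4, net.dec3, net.dec2, net.post_cdb]
        assert len(enc) == 5 and len(dec) == 5
        assert net.bottleneck is not None

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(variant="transformer", n_classes=4)


class TestForward:
    def test_shape_contract(self, rng):
        net = build_network(small_spec("affine"), seed=1)
        out = net.forward(rng.uniform(size=(2, 1, 32, 32)), res=ResolutionSpec((0.8, 0.8)))
        assert out.shape == (2, 4, 32, 32)

    def test_softmax_normalized_and_class_count(self, rng):
        net = build_network(small_spec("pool", n_classes=6), seed=1)
        out = net.forward(rng.uniform(size=(1, 1, 24, 24)))
        assert out.shape[1] == 6
        np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-5)

    def test_deterministic_within_batch(self, rng):
        net = build_network(small_spec("affine"), seed=2)
        x = rng.uniform(size=(1, 1, 20, 20))
        batch = np.concatenate([x, x])
        out = net.forward(batch, res=ResolutionSpec((1.0, 1.0)))
        np.testing.assert_array_equal(out.data[0], out.data[1])

    def test_rotated_internal_params_native_output(self, rng):
        net = build_network(small_spec("affine"), seed=3)
        x = rng.uniform(size=(1, 1, 20, 20))
        out = net.forward(
            x,
            res=ResolutionSpec((1.0, 1.0)),
            params=[InternalAugParams(theta=90.0)],
            training=True,
        )
        assert out.shape == (1, 4, 20, 20)
        assert np.all(np.isfinite(out.data))
        assert net.latent.pending == 0  # every forward has its paired inverse

    def test_finite_forward_random_inputs(self, rng):
        for variant in ("pool", "scale", "affine"):
            net = build_network(small_spec(variant), seed=4)
            out = net.forward(rng.uniform(size=(2, 1, 17, 17)), res=ResolutionSpec((0.9, 0.9)))
            assert np.all(np.isfinite(out.data))

    def test_scale_variant_rejects_rotation_params(self, rng):
        net = build_network(small_spec("scale"), seed=0)
        with pytest.raises(ValueError):
            net.forward(
                rng.uniform(size=(1, 1, 16, 16)),
                res=ResolutionSpec((1.0, 1.0)),
                params=[InternalAugParams(theta=5.0)],
                training=True,
            )

    def test_missing_resolution_rejected(self, rng):
        net = build_network(small_spec("affine"), seed=0)
        with pytest.raises(ValueError, match="ResolutionSpec"):
            net.forward(rng.uniform(size=(1, 1, 16, 16)))

    def test_weight_copy_equivalence_bypassed_transitions(self, rng):
        """With the first/last transition bypassed in both, the affine
        variant under copied weights reproduces the pooling variant exactly
        (res_native = res_inner, no internal augmentation)."""
        s_pool = small_spec("pool", bypass_first_transition=True)
        s_aff = small_spec("affine", bypass_first_transition=True)
        a = build_network(s_pool, seed=5)
        b = build_network(s_aff, seed=99)
        state = a.state_dict()
        # keys embed no variant information, so the census matches
        state = {k: v for k, v in state.items()}
        b.load_state_dict(state)
        x = rng.uniform(size=(2, 1, 24, 24))
        out_a = a.forward(x)
        out_b = b.forward(x, res=ResolutionSpec((0.8, 0.8)))
        np.testing.assert_allclose(out_a.data, out_b.data, atol=1e-5)

    def test_checkpoint_structure_shared_across_variants(self, rng):
        """A scale-variant state loads into an affine net (shared blocks)."""
        a = build_network(small_spec("scale"), seed=0)
        b = build_network(small_spec("affine"), seed=1)
        b.load_state_dict(a.state_dict())
        x = rng.uniform(size=(1, 1, 16, 16))
        res = ResolutionSpec((0.8, 0.8))
        np.testing.assert_allclose(
            a.forward(x, res=res).data, b.forward(x, res=res).data, atol=1e-6
        )
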