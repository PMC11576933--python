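"""Encoder-decoder segmentation networks with competitive dense blocks.

Three parameter-equal variants of one macro-architecture (five encoder and
five decoder blocks around a bottleneck, 3x3 same-padding convolutions,
maxout feature competition, index-preserving pool/unpool):

``pool``
    every scale transition is 2x2 max-pooling / index-unpooling (the
    fixed-resolution baseline);
``scale``
    the first/last transition is the latent transform restricted to
    resolution normalization (scaling only, optional ``alpha`` jitter);
``affine``
    the first/last transition is the full 4-DOF transform module
    (scale + in-plane rotation + translation), applied to feature maps and
    exactly inverted before the last decoder block.

The scale transitions carry no learnable parameters, so all variants have
identical parameter censuses and interchangeable checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import ResolutionSpec
from .latent import InternalAugParams, InternalAugRanges, LatentTransform

__all__ = ["NetworkSpec", "SegNet", "build_network", "VARIANTS"]

VARIANTS = ("pool", "scale", "affine")


@dataclass(frozen=True)
class NetworkSpec:
    variant: str
    n_classes: int
    in_channels: int = 1
    filters: int = 64
    res_inner: float = 0.8
    aug: InternalAugRanges = field(default_factory=InternalAugRanges)
    bn_momentum: float = 0.1
    bn_eps: float = 1e-5
    min_inner: int = 16
    #: test hook: make the first/last transition an identity in any variant,
    #: so weight-copied variants can be compared on one pathway.
    bypass_first_transition: bool = False

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.n_classes < 2 or self.filters < 1 or self.in_channels < 1:
            raise ValueError("n_classes, filters and in_channels must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        if isinstance(d.get("aug"), dict):
            d["aug"] = InternalAugRanges(**d["aug"])
        if isinstance(d.get("bypass_first_transition"), (int, bool)):
            d["bypass_first_transition"] = bool(d["bypass_first_transition"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Module:
    """Minimal layer container with recursive parameter discovery."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                out[key] = val
            elif isinstance(val, Module):
                out.update(val.parameters(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.parameters(prefix=f"{key}.{i}."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Module):
                out.update(val.buffers(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        out.update(item.buffers(prefix=f"{key}.{i}."))
            elif name.startswith("running_"):
                out[key] = val
        return out


#: network weights and activations run in single precision for speed; the
#: autodiff engine itself is dtype-agnostic (gradient checks use float64)
PARAM_DTYPE = np.float32


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        # Kaiming fan-in initialization matched to PReLU (a = 0.25)
        fan_in = cin * k * k
        std = np.sqrt(2.0 / (fan_in * (1 + 0.25 ** 2)))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(cout, cin, k, k)).astype(PARAM_DTYPE),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout, dtype=PARAM_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c, dtype=PARAM_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=PARAM_DTYPE), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        return ad.batchnorm(x, self.gamma, self.beta, mu, var, self.eps, training)


class PReLU(Module):
    def __init__(self, c: int, init: float = 0.25):
        self.slope = Tensor(np.full(c, init, dtype=PARAM_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.prelu(x, self.slope)


class CDB(Module):
    """Competitive dense block: four PReLU-Conv-BN sub-layers, each
    normalized output competing by maxout against the running skip."""

    #: structural order of the first sub-layer's operations (introspection)
    ops = ("prelu", "conv", "bn")

    def __init__(self, cin: int, f: int, rng: np.random.Generator,
                 momentum: float = 0.1, eps: float = 1e-5):
        self.prelus = [PReLU(cin)] + [PReLU(f) for _ in range(3)]
        self.convs = [Conv2d(cin, f, 3, rng)] + [Conv2d(f, f, 3, rng) for _ in range(3)]
        self.bns = [BatchNorm2d(f, momentum, eps) for _ in range(4)]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        s = self.bns[0](self.convs[0](self.prelus[0](x)), training)
        for k in range(1, 4):
            h = self.bns[k](self.convs[k](self.prelus[k](s)), training)
            s = ad.maximum(h, s)
        return s


class IDB(Module):
    """Input competitive dense block: raw inputs are normalized through a
    BN-Conv-BN head before the usual competitive sub-layers; used for the
    first two encoder blocks (pre-IDB and IDB)."""

    ops = ("bn", "conv", "bn")

    def __init__(self, cin: int, f: int, rng: np.random.Generator,
                 momentum: float = 0.1, eps: float = 1e-5):
        self.bn_in = BatchNorm2d(cin, momentum, eps)
        self.prelus = [PReLU(f) for _ in range(3)]
        self.convs = [Conv2d(cin, f, 3, rng)] + [Conv2d(f, f, 3, rng) for _ in range(3)]
        self.bns = [BatchNorm2d(f, momentum, eps) for _ in range(4)]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        s = self.bns[0](self.convs[0](self.bn_in(x, training)), training)
        for k in range(1, 4):
            h = self.bns[k](self.convs[k](self.prelus[k - 1](s)), training)
            s = ad.maximum(h, s)
        return s


class Classifier(Module):
    def __init__(self, f: int, n_classes: int, rng: np.random.Generator):
        self.conv = Conv2d(f, n_classes, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv(x)


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------

class SegNet(Module):
    """The macro-architecture shared by all variants (see module docstring)."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        f, m, e = spec.filters, spec.bn_momentum, spec.bn_eps
        self.enc1 = IDB(spec.in_channels, f, rng, m, e)   # pre-IDB (native space)
        self.enc2 = IDB(f, f, rng, m, e)                  # IDB (inner space)
        self.enc3 = CDB(f, f, rng, m, e)
        self.enc4 = CDB(f, f, rng, m, e)
        self.enc5 = CDB(f, f, rng, m, e)
        self.bottleneck = CDB(f, f, rng, m, e)
        self.dec5 = CDB(f, f, rng, m, e)
        self.dec4 = CDB(f, f, rng, m, e)
        self.dec3 = CDB(f, f, rng, m, e)
        self.dec2 = CDB(f, f, rng, m, e)
        self.post_cdb = CDB(2 * f, f, rng, m, e)          # after skip concatenation
        self.classifier = Classifier(f, spec.n_classes, rng)
        if spec.variant in ("scale", "affine"):
            self.latent = LatentTransform(
                allow_spatial=(spec.variant == "affine"), min_inner=spec.min_inner
            )
        else:
            self.latent = None

    # -- helpers -------------------------------------------------------------
    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters().values()))

    def zero_grad(self):
        for p in self.parameters().values():
            p.zero_grad()

    # -- forward -------------------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        res: ResolutionSpec | None = None,
        params: list[InternalAugParams] | None = None,
        training: bool = False,
    ) -> Tensor:
        """Run one batch of slices ``(N, C, H, W)`` to native-space per-class
        probabilities ``(N, n_classes, H, W)``.

        ``res`` is required for the ``scale``/``affine`` variants (the
        native-resolution contract); ``params`` supplies per-sample internal
        augmentation draws and defaults to the identity.
        """
        x = np.asarray(x, dtype=PARAM_DTYPE)
        if x.ndim != 4:
            raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        n = x.shape[0]
        spec = self.spec
        uses_latent = self.latent is not None and not spec.bypass_first_transition
        if uses_latent and res is None:
            raise ValueError(f"variant {spec.variant!r} requires a ResolutionSpec")
        if params is None:
            params = [InternalAugParams.identity()] * n
        if spec.variant != "affine":
            for p in params:
                if p.theta != 0.0 or p.translation != (0.0, 0.0):
                    raise ValueError(
                        f"variant {spec.variant!r} does not support internal "
                        "rotation/translation"
                    )

        xt = Tensor(x, requires_grad=True)
        e1 = self.enc1(xt, training)

        record = None
        if spec.bypass_first_transition:
            t1 = e1
        elif uses_latent:
            t1 = self.latent.forward_transition(e1, list(params), res)
            record = self.latent._pending[-1]
        else:
            t1, idx1, shape1 = ad.maxpool2x2(e1)

        e2 = self.enc2(t1, training)
        p2, idx2, shape2 = ad.maxpool2x2(e2)
        e3 = self.enc3(p2, training)
        p3, idx3, shape3 = ad.maxpool2x2(e3)
        e4 = self.enc4(p3, training)
        p4, idx4, shape4 = ad.maxpool2x2(e4)
        e5 = self.enc5(p4, training)
        p5, idx5, shape5 = ad.maxpool2x2(e5)
        b = self.bottleneck(p5, training)

        d5 = self.dec5(ad.maximum(ad.max_unpool2x2(b, idx5, shape5), e5), training)
        d4 = self.dec4(ad.maximum(ad.max_unpool2x2(d5, idx4, shape4), e4), training)
        d3 = self.dec3(ad.maximum(ad.max_unpool2x2(d4, idx3, shape3), e3), training)
        d2 = self.dec2(ad.maximum(ad.max_unpool2x2(d3, idx2, shape2), e2), training)

        if spec.bypass_first_transition:
            u1 = d2
        elif uses_latent:
            u1 = self.latent.inverse_transition(d2, record)
        else:
            u1 = ad.max_unpool2x2(d2, idx1, shape1)

        merged = self.post_cdb(ad.concat(u1, e1, axis=1), training)
        logits = self.classifier(merged)
        probs = ad.softmax(logits, axis=1)
        if not np.all(np.isfinite(probs.data)):
            raise FloatingPointError("non-finite activations in the final softmax")
        return probs

    __call__ = forward

    # -- state ----------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{k}": v.data.copy() for k, v in self.parameters().items()}
        state.update({f"buffer.{k}": v.copy() for k, v in self.buffers().items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        bufs = self.buffers()
        expected = {f"param.{k}" for k in params} | {f"buffer.{k}" for k in bufs}
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise KeyError(f"state mismatch: missing {sorted(missing)[:5]}, extra {sorted(extra)[:5]}")
        for k, p in params.items():
            arr = np.asarray(state[f"param.{k}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for k, buf in bufs.items():
            np.copyto(buf, state[f"buffer.{k}"])


def build_network(spec: NetworkSpec, seed: int = 0) -> SegNet:
    """Construct one of the three variants with seed-controlled weights."""
    return SegNet(spec, seed=seed)
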