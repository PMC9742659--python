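"""Nested residual-U-block network for direct NAC -> ASC PET image regression.

The architecture is a two-level nested U-shape: the outer encoder-decoder is a
classic U-Net, but every stage is itself a small U-shaped encoder-decoder with
a residual connection — a ReSidual U-block (RSU).  Each decoder stage and the
bottleneck emit a single-channel side output; the training loss supervises
every side output plus a fused output at equal weight (deep supervision), so
gradients reach all scales directly.

Differences from the saliency-detection original, chosen for SUV regression:
hidden activations are ReLU but output heads are linear (targets live in
[0, 5], not [0, 1]); upsampling is bilinear; no batch normalization (training
batches are small and federated aggregation of running statistics is out of
scope); and the network regresses residual corrections — every side output
and the fused output add the input slice to their predicted correction
field, with the fusion head zero-initialized, so training starts from the
identity mapping and learns the count restoration as a correction.  A zero
parameter vector therefore maps any input to itself.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from .nn import (
    ParameterVector,
    Tensor,
    add,
    add_losses,
    concat,
    conv2d,
    maxpool2,
    mse,
    relu,
    resize_bilinear,
)

__all__ = [
    "RSUConfig",
    "U2NetConfig",
    "U2Net",
    "desk_config",
    "full_config",
    "deep_supervision_loss",
]


@dataclass(frozen=True)
class RSUConfig:
    """One residual U-block: ``depth`` internal resolution levels.

    ``depth = 1`` degenerates to a residual block with no down/upsampling.
    The block's input spatial size must be divisible by ``2**(depth-1)``.
    """

    depth: int
    in_channels: int
    mid_channels: int
    out_channels: int
    dilated_bottom: bool = True

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("RSU depth must be >= 1")
        for n in (self.in_channels, self.mid_channels, self.out_channels):
            if n < 1:
                raise ValueError("channel counts must be positive")


@dataclass(frozen=True)
class U2NetConfig:
    """Outer topology: ``encoder[-1]`` is the bottleneck (bridge) stage.

    ``decoder`` is ordered deepest-first and must be one stage shorter than
    the encoder.  ``activation='linear'`` disables hidden nonlinearities
    (used by structural tests only).
    """

    encoder: tuple
    decoder: tuple
    activation: str = "relu"
    dtype: str = "float32"

    def __post_init__(self):
        if len(self.decoder) != len(self.encoder) - 1:
            raise ValueError("decoder must have exactly len(encoder) - 1 stages")
        if self.activation not in ("relu", "linear"):
            raise ValueError("activation must be 'relu' or 'linear'")
        S = len(self.encoder)
        for i in range(1, S):
            if self.encoder[i].in_channels != self.encoder[i - 1].out_channels:
                raise ValueError(f"encoder stage {i + 1} channel mismatch")
        prev = self.encoder[-1].out_channels
        for j, dc in zip(range(S - 1, 0, -1), self.decoder):
            want = prev + self.encoder[j - 1].out_channels
            if dc.in_channels != want:
                raise ValueError(
                    f"decoder stage {j} expects {want} input channels, got {dc.in_channels}"
                )
            prev = dc.out_channels

    @property
    def n_side_outputs(self) -> int:
        """Side outputs: one per decoder stage plus the bridge."""
        return len(self.decoder) + 1

    @property
    def required_divisor(self) -> int:
        """Input spatial sizes must be divisible by this (else padded)."""
        req = 1
        for i, ec in enumerate(self.encoder):
            req = max(req, 2 ** (i + ec.depth - 1))
        for j, dc in zip(range(len(self.encoder) - 1, 0, -1), self.decoder):
            req = max(req, 2 ** (j - 1 + dc.depth - 1))
        return req


def desk_config(base_width: int = 8, activation: str = "relu", dtype: str = "float32") -> U2NetConfig:
    """Small 3-stage (+bridge) configuration for 64x64 slices.

    Four side outputs (three decoder stages + bridge) plus the fused output.
    """
    w = base_width
    enc = (
        RSUConfig(3, 1, w // 2, w),
        RSUConfig(2, w, w // 2, 2 * w),
        RSUConfig(2, 2 * w, w, 2 * w),
        RSUConfig(1, 2 * w, w, 2 * w),  # bridge
    )
    dec = (
        RSUConfig(2, 4 * w, w, 2 * w),
        RSUConfig(2, 4 * w, w, 2 * w),
        RSUConfig(3, 3 * w, w // 2, w),
    )
    return U2NetConfig(enc, dec, activation=activation, dtype=dtype)


def micro_config(activation: str = "relu", dtype: str = "float64") -> U2NetConfig:
    """Tiny 1-stage (+bridge) float64 configuration for numerical-identity tests."""
    enc = (RSUConfig(2, 1, 2, 2), RSUConfig(1, 2, 2, 2))
    dec = (RSUConfig(2, 4, 2, 2),)
    return U2NetConfig(enc, dec, activation=activation, dtype=dtype)


def full_config(base_width: int = 16, dtype: str = "float32") -> U2NetConfig:
    """Publication-scale topology: 6 encoder stages, RSU depths 7-6-5-4 and
    dilated-bottom blocks at the two deepest stages."""
    w = base_width
    enc = (
        RSUConfig(7, 1, w, 2 * w),
        RSUConfig(6, 2 * w, w, 4 * w),
        RSUConfig(5, 4 * w, 2 * w, 8 * w),
        RSUConfig(4, 8 * w, 4 * w, 16 * w),
        RSUConfig(1, 16 * w, 8 * w, 16 * w),
        RSUConfig(1, 16 * w, 8 * w, 16 * w),  # bridge
    )
    dec = (
        RSUConfig(1, 32 * w, 8 * w, 16 * w),
        RSUConfig(4, 32 * w, 4 * w, 8 * w),
        RSUConfig(5, 16 * w, 2 * w, 4 * w),
        RSUConfig(6, 8 * w, w, 2 * w),
        RSUConfig(7, 4 * w, w, 2 * w),
    )
    return U2NetConfig(enc, dec, dtype=dtype)


class _Conv:
    """Named convolution layer: registers its parameter shapes."""

    def __init__(self, name, cin, cout, k=3, dilation=1):
        self.name = name
        self.k = k
        self.cin = cin
        self.cout = cout
        self.dilation = dilation

    def shapes(self) -> OrderedDict:
        return OrderedDict(
            [(f"{self.name}.w", (self.cout, self.cin, self.k, self.k)),
             (f"{self.name}.b", (self.cout,))]
        )

    def __call__(self, P, x):
        return conv2d(x, P[f"{self.name}.w"], P[f"{self.name}.b"], dilation=self.dilation)


class _RSU:
    def __init__(self, name: str, cfg: RSUConfig):
        self.cfg = cfg
        d, cin, mid, cout = cfg.depth, cfg.in_channels, cfg.mid_channels, cfg.out_channels
        self.conv_in = _Conv(f"{name}.in", cin, cout)
        self.enc = [_Conv(f"{name}.enc1", cout, mid)]
        self.enc += [_Conv(f"{name}.enc{i}", mid, mid) for i in range(2, d + 1)]
        self.bridge = _Conv(
            f"{name}.bridge", mid, mid, dilation=2 if cfg.dilated_bottom else 1
        )
        self.dec = [_Conv(f"{name}.dec{i}", 2 * mid, mid) for i in range(d, 1, -1)]
        self.dec.append(_Conv(f"{name}.dec1", 2 * mid, cout))

    def layers(self):
        return [self.conv_in, *self.enc, self.bridge, *self.dec]

    def __call__(self, P, x, act):
        d = self.cfg.depth
        H, W = x.data.shape[2:]
        div = 2 ** (d - 1)
        if H % div or W % div:
            raise ValueError(
                f"RSU of depth {d} requires spatial size divisible by {div}, got {H}x{W}"
            )
        hxin = act(self.conv_in(P, x))
        skips = [act(self.enc[0](P, hxin))]
        for i in range(1, d):
            skips.append(act(self.enc[i](P, maxpool2(skips[-1]))))
        h = act(self.bridge(P, skips[-1]))
        for i, dec in enumerate(self.dec):
            level = d - 1 - i  # skip index this decoder consumes
            if i > 0:
                h = resize_bilinear(h, skips[level].data.shape[2:])
            h = act(dec(P, concat([h, skips[level]])))
        return add(h, hxin)


def _crop(t: Tensor, H: int, W: int) -> Tensor:
    """Crop back to the pre-padding spatial size, with a gradient path."""
    out = Tensor(t.data[:, :, :H, :W], parents=(t,))

    def backward(g):
        if t.requires_grad:
            gp = np.zeros_like(t.data)
            gp[:, :, :H, :W] = g
            t._accumulate(gp)

    out._backward = backward
    return out


class U2Net:
    """The assembled network, operating on named or flat parameter vectors.

    Input/output contract: NAC slices normalized to [0, 5], shape
    (B, 1, H, W); fused and side outputs have the same spatial shape,
    unconstrained in sign (clip at export, not here).
    """

    def __init__(self, config: U2NetConfig):
        self.config = config
        self.dtype = np.dtype(config.dtype)
        S = len(config.encoder)
        self.enc_blocks = [_RSU(f"enc{i + 1}", c) for i, c in enumerate(config.encoder)]
        self.dec_blocks = [
            _RSU(f"dec{j}", c) for j, c in zip(range(S - 1, 0, -1), config.decoder)
        ]
        side_channels = [config.encoder[-1].out_channels] + [
            c.out_channels for c in config.decoder
        ]
        self.side_convs = [
            _Conv(f"side{i + 1}", ch, 1, k=3) for i, ch in enumerate(side_channels)
        ]
        self.fuse_conv = _Conv("fuse", len(side_channels), 1, k=1)
        self._shapes = OrderedDict()
        for blk in self.enc_blocks + self.dec_blocks:
            for layer in blk.layers():
                self._shapes.update(layer.shapes())
        for layer in [*self.side_convs, self.fuse_conv]:
            self._shapes.update(layer.shapes())
        self.template = ParameterVector(
            OrderedDict((k, np.zeros(s, dtype=self.dtype)) for k, s in self._shapes.items())
        )

    # -- parameters -----------------------------------------------------
    @property
    def n_params(self) -> int:
        return self.template.n_params

    def init_params(self, seed: int) -> ParameterVector:
        """He-normal weights, zero biases; deterministic in ``seed``."""
        rng = np.random.default_rng(seed)
        out = OrderedDict()
        for name, shape in self._shapes.items():
            if name.endswith(".b") or name.startswith("fuse."):
                # zero-init biases and the fusion head: training starts from
                # the identity mapping through the global residual skip
                out[name] = np.zeros(shape, dtype=self.dtype)
            else:
                cout, cin, k, _ = shape
                std = np.sqrt(2.0 / (cin * k * k))
                out[name] = rng.normal(0.0, std, size=shape).astype(self.dtype)
        return ParameterVector(out)

    def _wrap(self, theta, requires_grad=False):
        if isinstance(theta, np.ndarray):
            theta = self.template.from_flat(theta)
        return theta, {
            k: Tensor(v.astype(self.dtype, copy=False), requires_grad=requires_grad)
            for k, v in theta.items()
        }

    # -- forward --------------------------------------------------------
    def _act(self):
        return relu if self.config.activation == "relu" else (lambda t: t)

    def _forward_graph(self, P, x: np.ndarray):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        B, C, H, W = x.shape
        div = self.config.required_divisor
        ph, pw = (-H) % div, (-W) % div
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        act = self._act()
        h = Tensor(x)
        skips = []
        for i, blk in enumerate(self.enc_blocks):
            if i > 0:
                h = maxpool2(h)
            h = blk(P, h, act)
            skips.append(h)
        feats = [skips[-1]]  # bridge first, then decoder stages deep -> shallow
        h = skips[-1]
        S = len(self.enc_blocks)
        for j, blk in zip(range(S - 1, 0, -1), self.dec_blocks):
            h = resize_bilinear(h, skips[j - 1].data.shape[2:])
            h = blk(P, concat([h, skips[j - 1]]), act)
            feats.append(h)
        full = x.shape[2:]
        xt = Tensor(x[:, :1])  # global residual source (single-channel input)
        sides = [
            add(resize_bilinear(conv(P, f), full), xt)
            for conv, f in zip(self.side_convs, feats)
        ]
        fused = add(self.fuse_conv(P, concat(sides)), xt)
        if ph or pw:
            sides = [_crop(s, H, W) for s in sides]
            fused = _crop(fused, H, W)
        # shallow-to-deep ordering for the caller: decoder-1 ... bridge
        return fused, sides[::-1]

    def forward(self, theta, x: np.ndarray):
        """Inference forward pass: (fused, side_outputs) as numpy arrays."""
        _, P = self._wrap(theta, requires_grad=False)
        fused, sides = self._forward_graph(P, x)
        return fused.data, [s.data for s in sides]

    def predict(self, theta, x: np.ndarray, clip: bool = False) -> np.ndarray:
        fused, _ = self.forward(theta, x)
        return np.clip(fused, 0, None) if clip else fused

    def loss(self, theta, X: np.ndarray, Y: np.ndarray) -> float:
        """Deep-supervision L2 loss of the batch, without gradients."""
        fused, sides = self.forward(theta, X)
        Y = np.asarray(Y, dtype=self.dtype)
        if Y.ndim == 2:
            Y = Y[None, None]
        elif Y.ndim == 3:
            Y = Y[:, None]
        return deep_supervision_loss(sides, fused, Y)

    # -- training -------------------------------------------------------
    def loss_and_grad(self, theta, X: np.ndarray, Y: np.ndarray):
        """Deep-supervision L2 loss and its gradient, both over the batch.

        Returns ``(loss, grad)`` where ``grad`` matches the type of ``theta``
        (flat ndarray in, flat ndarray out).
        """
        flat_in = isinstance(theta, np.ndarray)
        pv, P = self._wrap(theta, requires_grad=True)
        fused, sides = self._forward_graph(P, X)
        Y = np.asarray(Y, dtype=self.dtype)
        if Y.ndim == 3:
            Y = Y[:, None]
        loss = add_losses([mse(o, Y) for o in [*sides, fused]])
        loss.backward(np.asarray(1.0, dtype=self.dtype))
        grads = OrderedDict(
            (k, P[k].grad if P[k].grad is not None else np.zeros_like(pv[k]))
            for k in pv
        )
        gvec = ParameterVector(grads)
        return float(loss.data), (gvec.to_flat() if flat_in else gvec)


def deep_supervision_loss(side_outputs, fused, target) -> float:
    """Equal-weight sum of per-head mean squared errors (all sides + fused)."""
    target = np.asarray(target)
    total = 0.0
    for out in [*side_outputs, fused]:
        out = np.asarray(out)
        if out.shape != target.shape:
            raise ValueError(
                f"output shape {out.shape} not conformable with target {target.shape}"
            )
        d = out - target
        total += float(np.mean(d * d))
    return total
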