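"""2D multi-view encoder-decoder networks built from competitive dense blocks.

Two families share one topology of four encoder blocks, a bottleneck and four
decoder blocks with 2x2 index-preserving max-pooling/unpooling between them:

* the **localization network** (5x5 kernels, no attention) segments a coarse
  ball-shaped region of interest on the 1.6 mm grid; decoder skips are fused
  by maxout competition;
* the **attention segmentation network** (3x3 kernels) segments OB tissue on
  96-cubed 0.8 mm crops; a positional self-attention module follows every
  block (4 encoder + bottleneck + 4 decoder = 9 modules) and decoder skips
  are fused by element-wise sum so multi-scale attention maps survive the
  unpooling path.

Both take stacks of three consecutive slices as input channels and emit
per-pixel class probabilities for the middle slice only.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .errors import ConfigurationError, ShapeError, SpecError
from .image_io import MultiSliceStack, PLANES
from .nn import autograd as ag
from .nn.autograd import Tensor, no_grad
from .nn.layers import (BatchNorm2d, Conv2d, Module, PReLU, SelfAttention2d,
                        maxout_fuse)


@dataclass(frozen=True)
class NetworkSpec:
    """Hyper-parameters of one per-view network.

    The two families are tied together: attention networks use 3x3 kernels
    and sum-fused skips; attention-free networks use 5x5 kernels and maxout
    skips.  ``filters`` is the channel width of every block body.
    """

    n_classes: int = 2
    filters: int = 64
    kernel: int = 5
    depth: int = 4
    attention: bool = False
    skip_fusion: str = "maxout"
    in_channels: int = 3

    def __post_init__(self):
        if self.attention and (self.skip_fusion != "sum" or self.kernel != 3):
            raise SpecError("attention networks require skip_fusion='sum' and kernel=3")
        if not self.attention and (self.skip_fusion != "maxout" or self.kernel != 5):
            raise SpecError("attention-free networks require skip_fusion='maxout' and kernel=5")
        if self.attention and self.filters % 8:
            raise SpecError("attention requires filters divisible by 8")
        if self.n_classes < 2 or self.depth < 1 or self.filters < 1:
            raise SpecError("invalid network spec")


def localization_spec(filters: int = 64, **kw) -> NetworkSpec:
    return NetworkSpec(filters=filters, kernel=5, attention=False,
                       skip_fusion="maxout", **kw)


def segmentation_spec(filters: int = 64, **kw) -> NetworkSpec:
    return NetworkSpec(filters=filters, kernel=3, attention=True,
                       skip_fusion="sum", **kw)


class CompetitiveDenseBlock(Module):
    """Three activation->convolution->normalisation sequences whose
    intermediate maps compete through element-wise maxima.

    The running maxout chain is: m1 = max(x1, x) (skipped in the first
    encoder block where the channel counts differ), m2 = max(x2, m1); the
    block returns the third normalised convolution output.  In the very first
    encoder block the leading activation is replaced by a batch-norm so raw
    image intensities are normalised before any competition.
    """

    def __init__(self, in_channels: int, spec: NetworkSpec,
                 rng: np.random.Generator, is_first: bool = False):
        super().__init__()
        f, k = spec.filters, spec.kernel
        self.is_first = is_first
        self.competitive_input = in_channels == f
        self.act1 = BatchNorm2d(in_channels) if is_first else PReLU(in_channels)
        self.conv1 = Conv2d(in_channels, f, k, rng)
        self.bn1 = BatchNorm2d(f)
        self.act2 = PReLU(f)
        self.conv2 = Conv2d(f, f, k, rng)
        self.bn2 = BatchNorm2d(f)
        self.act3 = PReLU(f)
        self.conv3 = Conv2d(f, f, k, rng)
        self.bn3 = BatchNorm2d(f)

    def forward(self, x: Tensor) -> Tensor:
        x1 = self.bn1(self.conv1(self.act1(x)))
        m1 = maxout_fuse(x1, x) if self.competitive_input else x1
        x2 = self.bn2(self.conv2(self.act2(m1)))
        m2 = maxout_fuse(x2, m1)
        return self.bn3(self.conv3(self.act3(m2)))


class ViewNet(Module):
    """One per-view encoder-decoder F-CNN (see module docstring)."""

    #: attention maps are N x N with N = H*W; restrict attention networks to
    #: the crop size they are designed for (N <= 96*96)
    MAX_ATTENTION_HW = 96

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        f = spec.filters
        self.encoders = [
            CompetitiveDenseBlock(spec.in_channels if i == 0 else f, spec, rng,
                                  is_first=(i == 0))
            for i in range(spec.depth)
        ]
        self.bottleneck = CompetitiveDenseBlock(f, spec, rng)
        self.decoders = [CompetitiveDenseBlock(f, spec, rng)
                         for _ in range(spec.depth)]
        if spec.attention:
            self.enc_att = [SelfAttention2d(f, rng) for _ in range(spec.depth)]
            self.bott_att = SelfAttention2d(f, rng)
            self.dec_att = [SelfAttention2d(f, rng) for _ in range(spec.depth)]
        self.classifier = Conv2d(f, spec.n_classes, 1, rng)

    def attention_modules(self):
        if not self.spec.attention:
            return []
        return [*self.enc_att, self.bott_att, *self.dec_att]

    def set_attention_norm_mode(self, mode: str):
        for m in self.attention_modules():
            m.norm_mode = mode

    def forward(self, x: Tensor) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        B, C, H, W = x.data.shape
        if C != self.spec.in_channels:
            raise ShapeError(f"expected {self.spec.in_channels} input channels, got {C}")
        step = 2 ** self.spec.depth
        if H % step or W % step:
            raise ShapeError(f"spatial size ({H},{W}) must be divisible by {step}")
        if self.spec.attention and max(H, W) > self.MAX_ATTENTION_HW:
            raise SpecError(f"attention networks accept at most "
                            f"{self.MAX_ATTENTION_HW}^2 pixels, got ({H},{W})")
        skips, indices = [], []
        h = x
        for i, block in enumerate(self.encoders):
            h = block(h)
            if self.spec.attention:
                h = self.enc_att[i](h)
            skips.append(h)
            h, idx = ag.max_pool2x2(h)
            indices.append(idx)
        h = self.bottleneck(h)
        if self.spec.attention:
            h = self.bott_att(h)
        for i, block in enumerate(self.decoders):
            h = ag.max_unpool2x2(h, indices[-1 - i])
            skip = skips[-1 - i]
            h = h + skip if self.spec.skip_fusion == "sum" else maxout_fuse(h, skip)
            h = block(h)
            if self.spec.attention:
                h = self.dec_att[i](h)
        logits = self.classifier(h)
        return ag.softmax(logits, axis=1)


def build_localization_net(spec: NetworkSpec | None = None,
                           rng: np.random.Generator | None = None) -> ViewNet:
    spec = spec or localization_spec()
    if spec.attention:
        raise SpecError("localization network must not use attention")
    return ViewNet(spec, rng if rng is not None else np.random.default_rng(0))


def build_segmentation_net(spec: NetworkSpec | None = None,
                           rng: np.random.Generator | None = None) -> ViewNet:
    spec = spec or segmentation_spec()
    if not spec.attention:
        raise SpecError("segmentation network requires attention")
    return ViewNet(spec, rng if rng is not None else np.random.default_rng(0))


def build_view_nets(spec: NetworkSpec, seed: int) -> dict:
    """One independently initialised network per anatomical view."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(PLANES))
    builder = build_segmentation_net if spec.attention else build_localization_net
    return {plane: builder(spec, np.random.default_rng(child))
            for plane, child in zip(PLANES, children)}


def _pad_to_multiple(arr: np.ndarray, step: int):
    H, W = arr.shape[-2:]
    ph = (-H) % step
    pw = (-W) % step
    pads = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2))
    if ph or pw:
        width = [(0, 0)] * (arr.ndim - 2) + list(pads)
        arr = np.pad(arr, width)
    return arr, pads


def forward_view(net: ViewNet, stacks: MultiSliceStack,
                 batch_size: int = 16) -> np.ndarray:
    """Run a per-view network over all slice stacks (inference mode).

    Returns per-slice class probabilities of shape (n_slices, n_classes, H, W)
    on the original slice grid; inputs are zero-padded to a multiple of the
    pooling footprint and the outputs cropped back.
    """
    if stacks.slabs.shape[1] != net.spec.in_channels:
        raise ShapeError("slab channel count mismatch")
    net.eval()
    step = 2 ** net.spec.depth
    out = []
    with no_grad():
        for start in range(0, stacks.slabs.shape[0], batch_size):
            batch = stacks.slabs[start:start + batch_size]
            padded, pads = _pad_to_multiple(batch, step)
            probs = net(Tensor(padded))
            probs = ag.crop2d(probs, pads)
            out.append(probs.data)
    return np.concatenate(out, axis=0)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(net: ViewNet, path, stage: str, view: str,
                    split: int | None = None, meta: dict | None = None):
    """Self-describing weight archive carrying the NetworkSpec that built it."""
    header = {"spec": asdict(net.spec), "stage": stage, "view": view,
              "split": split, "meta": meta or {}}
    np.savez_compressed(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **net.state_dict())


def load_checkpoint(path, expected_spec: NetworkSpec | None = None):
    """Rebuild a network from an archive, verifying spec compatibility.

    Returns ``(net, header)`` where header holds stage/view/split metadata.
    """
    with np.load(path) as archive:
        header = json.loads(bytes(archive["__header__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__header__"}
    spec = NetworkSpec(**header["spec"])
    if expected_spec is not None and spec != expected_spec:
        raise ConfigurationError(f"checkpoint spec {spec} != expected {expected_spec}")
    builder = build_segmentation_net if spec.attention else build_localization_net
    net = builder(spec, np.random.default_rng(0))
    net.load_state_dict(state)
    net.eval()
    return net, header
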