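"""GLCIC-style completion network and context discriminators.

The completion (generator) network is a fully convolutional encoder /
dilated-bottleneck / decoder: two stride-2 convolutions shrink the grid by
4x, four dilated convolutions (dilation 2, 4, 8, 16) widen the receptive
field without further downsampling, and two transposed convolutions restore
the original size. Every layer but the last is followed by ReLU; the output
layer applies a sigmoid so completed intensities live in [0, 1]. Because
there are no fully connected layers the same weights run at any input size.

Two discriminators judge realism: a *global* branch sees the whole slice, a
*local* branch sees only the generated strip regions. Their 1024-feature
vectors are concatenated and mapped to a single probability-of-real score.

The default layer tables reproduce the published architecture; the channel
counts can be scaled down uniformly (``base_channels``) so the same code
trains tiny CPU-sized configurations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .image import CTSlice
from .nn import Conv2d, ConvTranspose2d, Dense, Flatten, ReLU, Sequential, Sigmoid
from .preprocess import TruncationMask

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "CompletionOutput",
    "CompletionModel",
    "ContextDiscriminator",
    "build_completion",
    "build_discriminators",
    "complete",
    "default_completion_layers",
    "default_local_disc_layers",
    "default_global_disc_layers",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv | dilated_conv | deconv | output
    kernel: int
    dilation: int
    stride: int
    out_channels: int


def default_completion_layers() -> list[LayerSpec]:
    """The 17-layer completion table (output channel count is replaced by
    ``in_channels`` at build time for grayscale data)."""
    L = LayerSpec
    return [
        L("conv", 5, 1, 1, 64),
        L("conv", 3, 1, 2, 128),
        L("conv", 3, 1, 1, 128),
        L("conv", 3, 1, 2, 256),
        L("conv", 3, 1, 1, 256),
        L("conv", 3, 1, 1, 256),
        L("dilated_conv", 3, 2, 1, 256),
        L("dilated_conv", 3, 4, 1, 256),
        L("dilated_conv", 3, 8, 1, 256),
        L("dilated_conv", 3, 16, 1, 256),
        L("conv", 3, 1, 1, 256),
        L("conv", 3, 1, 1, 256),
        L("deconv", 4, 1, 2, 128),
        L("conv", 3, 1, 1, 128),
        L("deconv", 4, 1, 2, 64),
        L("conv", 3, 1, 1, 32),
        L("output", 3, 1, 1, 3),
    ]


def default_local_disc_layers() -> list[LayerSpec]:
    L = LayerSpec
    return [L("conv", 5, 1, 2, c) for c in (64, 128, 256, 512, 512)]


def default_global_disc_layers() -> list[LayerSpec]:
    L = LayerSpec
    return [L("conv", 5, 1, 2, c) for c in (64, 128, 256, 512, 512, 512)]


@dataclass
class NetworkSpec:
    """Architecture description.

    base_channels uniformly rescales every layer's channel count (floor 1),
    allowing tiny CPU configurations with the identical topology. fc_features
    is the per-branch discriminator feature width (1024 in the published
    tables), also scaled by base_channels.
    """

    in_channels: int = 1
    base_channels: float = 1.0
    completion_layers: list[LayerSpec] = field(default_factory=default_completion_layers)
    local_disc_layers: list[LayerSpec] = field(default_factory=default_local_disc_layers)
    global_disc_layers: list[LayerSpec] = field(default_factory=default_global_disc_layers)
    fc_features: int = 1024

    def scaled(self, c: int) -> int:
        return max(1, int(round(c * self.base_channels)))

    def validate(self) -> None:
        down = 1
        up = 1
        for ls in self.completion_layers:
            if ls.kind in ("conv", "dilated_conv", "output"):
                down *= ls.stride
            elif ls.kind == "deconv":
                up *= ls.stride
            else:
                raise ValueError(f"unknown layer kind {ls.kind!r}")
        if down != up:
            raise ValueError(
                f"completion strides do not restore the input size "
                f"(downscale x{down}, upscale x{up})"
            )
        if self.completion_layers[-1].kind != "output":
            raise ValueError("last completion layer must be the sigmoid output layer")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "NetworkSpec":
        d = json.loads(s)
        for key in ("completion_layers", "local_disc_layers", "global_disc_layers"):
            d[key] = [LayerSpec(**ls) for ls in d[key]]
        return cls(**d)

    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()


@dataclass
class CompletionOutput:
    """raw: the network's full-frame prediction in [0, 1]; composited: known
    pixels copied verbatim from the input, missing pixels from raw."""

    raw: np.ndarray
    composited: np.ndarray


def _build_layers(spec: NetworkSpec, table: list[LayerSpec], in_ch: int, rng) -> Sequential:
    layers = []
    ch = in_ch
    for ls in table:
        out = spec.scaled(ls.out_channels)
        if ls.kind in ("conv", "dilated_conv"):
            layers.append(Conv2d(ch, out, ls.kernel, stride=ls.stride,
                                 dilation=ls.dilation, rng=rng))
            layers.append(ReLU())
        elif ls.kind == "deconv":
            layers.append(ConvTranspose2d(ch, out, kernel=ls.kernel, stride=ls.stride, rng=rng))
            layers.append(ReLU())
        elif ls.kind == "output":
            out = spec.in_channels  # grayscale output, one channel per input channel
            layers.append(Conv2d(ch, out, ls.kernel, stride=ls.stride,
                                 dilation=ls.dilation, rng=rng))
            layers.append(Sigmoid())
        ch = out
    return Sequential(layers)


class CompletionModel:
    """Completion network handle: masked image + mask channel in, [0,1]
    prediction out."""

    def __init__(self, spec: NetworkSpec, rng=None):
        spec.validate()
        self.spec = spec
        rng = rng or np.random.default_rng()
        self.net = _build_layers(spec, spec.completion_layers, spec.in_channels + 1, rng)

    def forward(self, masked: np.ndarray, missing: np.ndarray) -> np.ndarray:
        """masked: (B,H,W,1) in [0,1]; missing: (B,H,W,1) binary, 1 = hole."""
        x = np.concatenate([masked, missing], axis=-1).astype(np.float32)
        return self.net.forward(x)

    def backward(self, d_raw: np.ndarray) -> np.ndarray:
        return self.net.backward(d_raw)

    def params(self):
        return self.net.params()

    def zero_grad(self):
        self.net.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())


def build_completion(spec: NetworkSpec, rng=None) -> CompletionModel:
    return CompletionModel(spec, rng=rng)


def _branch_feature_hw(table, spec, size_hw):
    h, w = size_hw
    for ls in table:
        h = (h + 2 * (ls.kernel // 2) - ls.kernel) // ls.stride + 1
        w = (w + 2 * (ls.kernel // 2) - ls.kernel) // ls.stride + 1
    if h < 1 or w < 1:
        raise ValueError(
            f"input size {size_hw} collapses below 1x1 in the discriminator"
        )
    return h, w


class ContextDiscriminator:
    """Global + local context discriminators with a concatenation head.

    The global branch consumes the full image; the local branch consumes one
    full-height crop per truncation strip (the two strip features are
    averaged). Branch features (fc_features each) are concatenated and mapped
    by a single fully connected layer with sigmoid to a realism score in
    (0, 1) per batch item.
    """

    def __init__(self, spec: NetworkSpec, image_hw: tuple[int, int],
                 patch_hw: tuple[int, int], rng=None):
        rng = rng or np.random.default_rng()
        self.spec = spec
        self.image_hw = tuple(image_hw)
        self.patch_hw = tuple(patch_hw)
        fc = spec.scaled(spec.fc_features)

        def branch(table, hw):
            seq = _build_layers_disc(spec, table, spec.in_channels, rng)
            h, w = _branch_feature_hw(table, spec, hw)
            ch = spec.scaled(table[-1].out_channels)
            seq.layers.append(Flatten())
            seq.layers.append(Dense(h * w * ch, fc, rng=rng))
            seq.layers.append(ReLU())
            return seq

        self.global_branch = branch(spec.global_disc_layers, self.image_hw)
        self.local_branch = branch(spec.local_disc_layers, self.patch_hw)
        self.head = Dense(2 * fc, 1, rng=rng)
        self.head_act = Sigmoid()
        self._fc = fc

    def forward(self, images: np.ndarray, crops: np.ndarray) -> np.ndarray:
        """images: (B,H,W,C); crops: (S,B,h,w,C), one entry per strip.
        Returns scores (B,) in (0,1)."""
        B = images.shape[0]
        S = crops.shape[0]
        gf = self.global_branch.forward(images.astype(np.float32))
        stacked = crops.reshape(S * B, *crops.shape[2:]).astype(np.float32)
        lf_all = self.local_branch.forward(stacked).reshape(S, B, self._fc)
        lf = lf_all.mean(axis=0)
        self._S = S
        feat = np.concatenate([gf, lf], axis=1)
        score = self.head_act.forward(self.head.forward(feat))
        return score[:, 0]

    def backward(self, dscore: np.ndarray):
        """dscore: (B,). Returns (dimages, dcrops) matching forward inputs."""
        dfeat = self.head.backward(self.head_act.backward(dscore[:, None]))
        fc = self._fc
        dgf, dlf = dfeat[:, :fc], dfeat[:, fc:]
        dimages = self.global_branch.backward(dgf)
        S = self._S
        B = dlf.shape[0]
        dlf_all = np.broadcast_to(dlf / S, (S, B, fc)).reshape(S * B, fc)
        dcrops = self.local_branch.backward(np.ascontiguousarray(dlf_all))
        return dimages, dcrops.reshape(S, B, *dcrops.shape[1:])

    def params(self):
        return (self.global_branch.params() + self.local_branch.params()
                + self.head.params())

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0


def _build_layers_disc(spec: NetworkSpec, table, in_ch, rng) -> Sequential:
    layers = []
    ch = in_ch
    for ls in table:
        out = spec.scaled(ls.out_channels)
        layers.append(Conv2d(ch, out, ls.kernel, stride=ls.stride,
                             dilation=ls.dilation, rng=rng))
        layers.append(ReLU())
        ch = out
    return Sequential(layers)


def local_patch_bounds(mask: TruncationMask, min_frac: float = 0.25) -> list[tuple[int, int]]:
    """Column ranges of the local-discriminator crops: one full-height crop
    per truncation strip, width max(strip width, grid_size * min_frac)."""
    g = mask.grid_size
    width = max(mask.left_cols, mask.right_cols, int(round(g * min_frac)))
    bounds = []
    if mask.left_cols > 0 or (mask.left_cols == 0 and mask.right_cols == 0):
        bounds.append((0, width))
    if mask.right_cols > 0:
        bounds.append((g - width, g))
    return bounds


def extract_local_crops(images: np.ndarray, mask: TruncationMask) -> np.ndarray:
    """(B,H,W,C) -> (S,B,H,w,C) stack of per-strip crops."""
    bounds = local_patch_bounds(mask)
    return np.stack([images[:, :, a:b, :] for a, b in bounds], axis=0)


def build_discriminators(spec: NetworkSpec, image_hw: tuple[int, int],
                         mask: TruncationMask, rng=None) -> ContextDiscriminator:
    bounds = local_patch_bounds(mask)
    width = bounds[0][1] - bounds[0][0]
    return ContextDiscriminator(spec, image_hw, (image_hw[0], width), rng=rng)


def composite(raw: np.ndarray, masked: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Copy known pixels from the input, take missing pixels from raw."""
    return masked * (1.0 - missing) + raw * missing


def complete(model: CompletionModel, masked: CTSlice, mask: TruncationMask) -> CompletionOutput:
    """Run the completion network on one masked slice.

    The slice must be in normalized01 units; known pixels of the composited
    output are bit-identical to the input.
    """
    if masked.unit != "normalized01":
        raise ValueError(
            "complete() expects a normalized01 slice; convert with "
            "CTSlice.to_normalized01() first"
        )
    if masked.pixels.shape != mask.known.shape:
        raise ValueError("slice and mask shapes differ")
    missing = (~mask.known.astype(bool)).astype(np.float32)[None, :, :, None]
    x = masked.pixels.astype(np.float32)[None, :, :, None]
    raw = model.forward(x * (1.0 - missing), missing)
    comp = composite(raw, x, missing)
    comp[missing == 0] = x[missing == 0]  # exact copy, no float round-trip
    return CompletionOutput(raw=raw[0, :, :, 0], composited=comp[0, :, :, 0])


def _collect_weights(model_params, prefix):
    return {f"{prefix}{i}": p for i, (p, _) in enumerate(model_params)}


def save_checkpoint(path, model: CompletionModel, disc: ContextDiscriminator | None = None):
    """Single-file checkpoint embedding the architecture spec; loading
    verifies the spec hash."""
    arrays = _collect_weights(model.params(), "g")
    if disc is not None:
        arrays.update(_collect_weights(disc.params(), "d"))
    meta = {
        "spec": model.spec.to_json(),
        "spec_hash": model.spec.hash(),
        "has_disc": disc is not None,
        "image_hw": list(disc.image_hw) if disc is not None else None,
        "patch_hw": list(disc.patch_hw) if disc is not None else None,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path, with_disc: bool = False):
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    spec = NetworkSpec.from_json(meta["spec"])
    if spec.hash() != meta["spec_hash"]:
        raise ValueError("checkpoint spec hash mismatch: file corrupt or edited")
    model = CompletionModel(spec, rng=np.random.default_rng(0))
    for i, (p, _) in enumerate(model.params()):
        p[...] = data[f"g{i}"]
    if not with_disc:
        return model
    if not meta["has_disc"]:
        raise ValueError("checkpoint holds no discriminator weights")
    disc = ContextDiscriminator(spec, tuple(meta["image_hw"]), tuple(meta["patch_hw"]),
                                rng=np.random.default_rng(0))
    for i, (p, _) in enumerate(disc.params()):
        p[...] = data[f"d{i}"]
    return model, disc
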