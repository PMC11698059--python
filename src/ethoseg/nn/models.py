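"""V-Net and U-Net 1-D encoder-decoder segmentation architectures.

Both families map an ``(nb_desc, WS)`` sensor window to per-timestep class
logits of shape ``(nb_behaviors, WS)``; a softmax over the class axis turns
each timestep into a probability distribution.

Layer plans (kernel 3, stride 1, same-padding, ReLU; features double per
level from ``depth``):

* V-Net (3 levels): 3 encoder blocks x 2 convs, a 2-conv bottleneck,
  3 decoder blocks x 2 convs, and a 1x1 head conv -> 15 convolutional
  layers.  Downsampling is max-pooling, upsampling is non-learned
  nearest-neighbour repetition, so neither adds to the conv census.
* U-Net (4 levels): 4 encoder blocks x 2 convs, a 2-conv bottleneck,
  4 decoder blocks of (learned kernel-2 stride-2 up-conv + 2 convs), and a
  1x1 head conv -> 23 convolutional layers.

Skip connections concatenate encoder features onto the upsampled decoder
path at each level.  Parameter groups are named ``encoder{i}``,
``bottleneck``, ``decoder{i}`` and ``head`` so freeze plans and head surgery
address them explicitly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .layers import Conv1d, ConvTranspose1d, Layer, MaxPool1d, Param, Upsample1d

FAMILY_LEVELS = {"vnet": 3, "unet": 4}


class SpecError(ValueError):
    """Invalid architecture specification."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of a segmentation network."""

    family: str  # "vnet" | "unet"
    ws: int  # window size, samples
    nb_desc: int  # input channels
    nb_behaviors: int  # output classes
    depth: int = 32  # base feature count

    def __post_init__(self) -> None:
        if self.family not in FAMILY_LEVELS:
            raise SpecError(f"unknown family {self.family!r}")
        levels = FAMILY_LEVELS[self.family]
        if self.ws % (2**levels) != 0:
            raise SpecError(
                f"ws={self.ws} must be divisible by 2^{levels} for {self.family}")
        if self.nb_desc < 1 or self.nb_behaviors < 2 or self.depth < 1:
            raise SpecError("need nb_desc >= 1, nb_behaviors >= 2, depth >= 1")

    @property
    def levels(self) -> int:
        return FAMILY_LEVELS[self.family]


class Scenario(str, Enum):
    """Transfer-learning scenarios (which parameter groups stay trainable)."""

    SCRATCH = "scratch"  # random init, all trainable
    TL_ALL = "all"  # source weights, all fine-tuned
    TL_FREEZE_ENCODER = "freeze-encoder"  # encoder (+bottleneck) frozen
    TL_FREEZE_DECODER = "freeze-decoder"  # decoder blocks frozen
    TL_HEAD_ONLY = "head-only"  # only the final conv fine-tuned


@dataclass
class FreezePlan:
    """Per-parameter-group trainability mask for one scenario."""

    scenario: Scenario
    trainable: dict[str, bool]

    @classmethod
    def for_model(cls, scenario: Scenario, model: "SegModel") -> "FreezePlan":
        names = list(model.groups)
        encoder = [g for g in names if g.startswith("encoder")] + ["bottleneck"]
        decoder = [g for g in names if g.startswith("decoder")]
        if scenario in (Scenario.SCRATCH, Scenario.TL_ALL):
            mask = {g: True for g in names}
        elif scenario is Scenario.TL_FREEZE_ENCODER:
            mask = {g: g not in encoder for g in names}
        elif scenario is Scenario.TL_FREEZE_DECODER:
            mask = {g: g not in decoder for g in names}
        elif scenario is Scenario.TL_HEAD_ONLY:
            mask = {g: g == "head" for g in names}
        else:  # pragma: no cover
            raise ValueError(scenario)
        return cls(scenario=scenario, trainable=mask)


class SegModel:
    """Realized weights + topology for one :class:`ArchitectureSpec`."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d, levels = spec.depth, spec.levels
        ch = [spec.nb_desc] + [d * 2**i for i in range(levels + 1)]

        self.enc_blocks: list[list[Conv1d]] = []
        self.pools: list[MaxPool1d] = []
        for i in range(levels):
            self.enc_blocks.append([
                Conv1d(f"encoder{i + 1}.conv1", ch[i], ch[i + 1], rng=rng),
                Conv1d(f"encoder{i + 1}.conv2", ch[i + 1], ch[i + 1], rng=rng),
            ])
            self.pools.append(MaxPool1d())
        self.bottleneck = [
            Conv1d("bottleneck.conv1", ch[levels], ch[levels + 1], rng=rng),
            Conv1d("bottleneck.conv2", ch[levels + 1], ch[levels + 1], rng=rng),
        ]
        # decoder level i (0 = shallowest) receives up(ch_above) ++ skip(ch[i+1])
        self.up_layers: list[Layer] = []
        self.dec_blocks: list[list[Conv1d]] = []
        for i in range(levels):
            c_above = ch[i + 2]
            c_skip = ch[i + 1]
            if spec.family == "unet":
                up: Layer = ConvTranspose1d(f"decoder{i + 1}.upconv",
                                            c_above, c_skip, rng=rng)
                c_up = c_skip
            else:
                up = Upsample1d()
                c_up = c_above
            self.up_layers.append(up)
            self.dec_blocks.append([
                Conv1d(f"decoder{i + 1}.conv1", c_up + c_skip, c_skip, rng=rng),
                Conv1d(f"decoder{i + 1}.conv2", c_skip, c_skip, rng=rng),
            ])
        self.head = Conv1d("head.conv", ch[1], spec.nb_behaviors, kernel=1,
                           relu=False, rng=rng)
        # fixed per-channel input standardization (buffers, not parameters);
        # estimated once from the training split and carried with the weights
        self.input_offset = np.zeros(spec.nb_desc, dtype=np.float32)
        self.input_scale = np.ones(spec.nb_desc, dtype=np.float32)
        self._up_channels = [
            ch[i + 1] if spec.family == "unet" else ch[i + 2]
            for i in range(levels)
        ]

    # -- structure ---------------------------------------------------------

    @property
    def groups(self) -> dict[str, list[Param]]:
        out: dict[str, list[Param]] = {}
        for i, blk in enumerate(self.enc_blocks):
            out[f"encoder{i + 1}"] = [p for l in blk for p in l.params()]
        out["bottleneck"] = [p for l in self.bottleneck for p in l.params()]
        for i in range(self.spec.levels):
            params = list(self.up_layers[i].params())
            params += [p for l in self.dec_blocks[i] for p in l.params()]
            out[f"decoder{i + 1}"] = params
        out["head"] = self.head.params()
        return out

    def parameters(self) -> list[Param]:
        return [p for params in self.groups.values() for p in params]

    def _all_layers(self) -> list[Layer]:
        layers: list[Layer] = []
        for blk in self.enc_blocks:
            layers.extend(blk)
        layers.extend(self.pools)
        layers.extend(self.bottleneck)
        layers.extend(self.up_layers)
        for blk in self.dec_blocks:
            layers.extend(blk)
        layers.append(self.head)
        return layers

    @property
    def conv_layer_count(self) -> int:
        """Programmatic census of layers performing (learned) convolution."""
        return sum(1 for l in self._all_layers() if getattr(l, "is_conv", False))

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Input (n, nb_desc, ws) -> logits (n, nb_behaviors, ws)."""
        if x.ndim == 2:
            x = x[None]
        if x.shape[1] != self.spec.nb_desc or x.shape[2] != self.spec.ws:
            raise ValueError(
                f"expected input (*, {self.spec.nb_desc}, {self.spec.ws}), "
                f"got {x.shape}")
        h = (x.astype(np.float32) - self.input_offset[None, :, None]) \
            / self.input_scale[None, :, None]
        h = np.ascontiguousarray(h)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            for layer in blk:
                h = layer.forward(h)
            skips.append(h)
            h = pool.forward(h)
        for layer in self.bottleneck:
            h = layer.forward(h)
        for i in range(self.spec.levels - 1, -1, -1):
            h = self.up_layers[i].forward(h)
            h = np.concatenate([h, skips[i]], axis=1)
            for layer in self.dec_blocks[i]:
                h = layer.forward(h)
        return self.head.forward(h)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(logits); accumulates parameter gradients."""
        dh = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * self.spec.levels
        for i in range(self.spec.levels):
            for layer in reversed(self.dec_blocks[i]):
                dh = layer.backward(dh)
            c_up = self._up_channels[i]
            du, dskips[i] = dh[:, :c_up], dh[:, c_up:]
            dh = self.up_layers[i].backward(np.ascontiguousarray(du))
        for layer in reversed(self.bottleneck):
            dh = layer.backward(dh)
        for i in range(self.spec.levels - 1, -1, -1):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            for layer in reversed(self.enc_blocks[i]):
                dh = layer.backward(dh)
        return dh

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Input (n, nb_desc, ws) -> per-timestep probabilities (n, ws, C)."""
        logits = self.forward(x)
        z = logits.transpose(0, 2, 1).astype(np.float64)
        z = z - z.max(axis=2, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=2, keepdims=True)

    # -- weights -----------------------------------------------------------

    def set_input_norm(self, mean: np.ndarray, sd: np.ndarray) -> None:
        """Fix the per-channel standardization applied before the first conv."""
        self.input_offset = np.asarray(mean, dtype=np.float32).copy()
        self.input_scale = np.clip(np.asarray(sd, dtype=np.float32), 1e-6, None)

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {p.name: p.value.copy() for p in self.parameters()}
        out["input.offset"] = self.input_offset.copy()
        out["input.scale"] = self.input_scale.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        if "input.offset" in weights:
            self.input_offset = np.asarray(weights["input.offset"],
                                           dtype=np.float32).copy()
            self.input_scale = np.asarray(weights["input.scale"],
                                          dtype=np.float32).copy()
        for p in self.parameters():
            if p.name not in weights:
                raise KeyError(f"missing weight array {p.name}")
            if weights[p.name].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value = np.ascontiguousarray(weights[p.name], dtype=np.float32).copy()

    def weights_hash(self, group: str | None = None) -> str:
        params = self.groups[group] if group else self.parameters()
        h = hashlib.sha256()
        for p in sorted(params, key=lambda q: q.name):
            h.update(p.name.encode())
            h.update(np.ascontiguousarray(p.value).tobytes())
        if group is None:
            h.update(self.input_offset.tobytes())
            h.update(self.input_scale.tobytes())
        return h.hexdigest()


def build_model(spec: ArchitectureSpec, seed: int = 0) -> SegModel:
    """Realize an architecture with seeded fan-in-uniform weights."""
    return SegModel(spec, seed=seed)


def clone_model(model: SegModel, seed: int = 0) -> SegModel:
    out = SegModel(model.spec, seed=seed)
    out.set_weights(model.get_weights())
    return out


def replace_head(model: SegModel, new_nb_behaviors: int,
                 seed: int = 0) -> SegModel:
    """Swap the final conv for one with ``new_nb_behaviors`` channels.

    All non-head weights are carried over bit-exactly; the new head is
    freshly initialized (seeded).
    """
    if new_nb_behaviors < 2:
        raise SpecError("new_nb_behaviors must be >= 2")
    new_spec = dataclasses.replace(model.spec, nb_behaviors=new_nb_behaviors)
    out = SegModel(new_spec, seed=seed)
    weights = model.get_weights()
    head_names = {p.name for p in model.groups["head"]}
    for p in out.parameters():
        if p.name in weights and p.name not in head_names:
            p.value = np.ascontiguousarray(weights[p.name]).copy()
    out.input_offset = model.input_offset.copy()
    out.input_scale = model.input_scale.copy()
    return out


def apply_freeze_plan(model: SegModel, plan: FreezePlan) -> SegModel:
    """Set per-group trainability flags in place (returns the model)."""
    for group, params in model.groups.items():
        flag = plan.trainable.get(group, True)
        for p in params:
            p.trainable = flag
    return model
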