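"""Densely-connected convolutional denoiser for reduced-count planar images.

The architecture follows the DenseNet-for-restoration lineage: one
convolution extracting low-level features, a stack of dense blocks whose
layers each receive the concatenation of *all* preceding feature maps, a
1x1 bottleneck, two further convolution stages standing in for the
deconvolution (upscaling) stages of the super-resolution original -- input
and output share resolution here, so both run at stride 1 -- and a single
channel reconstruction layer.  Weights are He/MSRA-initialized, biases
zero, the loss is the RMSE between the network output and the full-count
label in normalized units, and optimization is Adam.

Intensity convention: a reduced-count image acquired at count fraction
``f`` is divided by ``f`` before entering the network, so the network
always works at full-count intensity scale and only removes noise.  This
is what makes a *single* model serve all fractions: the reference
time-point identities of the emulated study (the 96 h full-count image is
statistically the 60%-count 24 h image, yet its denoised outputs sit at
the 96 h level) are only consistent with scale-corrected inputs.  The
remaining global normalization to [0, 1]-ish range uses a constant stored
with the model (99.9th percentile of the training labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .projector import CountImage


@dataclass
class NetworkSpec:
    """Denoiser topology.

    The full-scale recipe uses 8 blocks of 8 convolutions; the desk-scale
    profile (:data:`DESK_SPEC`) reduces this to 2 blocks of 4 for CPU
    training.  Growth and filter counts are not fixed by the recipe and
    default to the restoration-DenseNet lineage values.
    """

    n_blocks: int = 8
    convs_per_block: int = 8
    growth: int = 16
    low_level_filters: int = 16
    bottleneck_filters: int = 256
    upscale_stages: int = 2
    kernel_size: int = 3

    def __post_init__(self) -> None:
        for v in (self.n_blocks, self.convs_per_block, self.growth,
                  self.low_level_filters, self.bottleneck_filters,
                  self.upscale_stages, self.kernel_size):
            if v < 1:
                raise ValueError("all architecture counts must be >= 1")

    @property
    def n_weighted_layers(self) -> int:
        """Convolution-layer count: low + blocks + bottleneck + upscale +
        reconstruction (69 for the full-scale recipe)."""
        return 1 + self.n_blocks * self.convs_per_block + 1 \
            + self.upscale_stages + 1


#: full-scale (GPU-class) profile of the emulated recipe
PAPER_SPEC = NetworkSpec()

#: reduced profile for CPU-scale experiments
DESK_SPEC = NetworkSpec(n_blocks=2, convs_per_block=4, growth=8,
                        low_level_filters=8, bottleneck_filters=16)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    momentum: float = 0.9       # Adam beta1
    weight_decay: float = 1e-4
    batch_size: int = 32
    iterations: int = 2000
    seed: int = 0
    normalization_constant: float | None = None  # counts -> [0, 1] scale

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if self.batch_size < 1 or self.iterations < 0:
            raise ValueError("batch_size >= 1 and iterations >= 0 required")


@dataclass
class PatchDataset:
    """Co-located input/label 25x25 patch pairs with provenance."""

    inputs: np.ndarray   # (M, size, size) float32, scale-corrected counts
    labels: np.ndarray   # (M, size, size) float32, full-count
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.float32)
        if self.inputs.shape != self.labels.shape:
            raise ValueError("inputs and labels must share shape")

    def __len__(self) -> int:
        return len(self.inputs)

    @staticmethod
    def concatenate(parts: Sequence["PatchDataset"]) -> "PatchDataset":
        return PatchDataset(
            np.concatenate([p.inputs for p in parts]),
            np.concatenate([p.labels for p in parts]),
            sum((p.provenance for p in parts), []))


def extract_patches(input_img: np.ndarray, label_img: np.ndarray,
                    size: int = 25, stride: int = 25,
                    offset: tuple[int, int] | None = None,
                    rng: np.random.Generator | None = None,
                    image_id: str = "") -> PatchDataset:
    """Cut co-located patch pairs on a stride grid.

    The grid starts at ``offset``; when unset, a random per-image offset in
    ``[0, stride)`` is drawn (stride-25 tiles never overlap, yet placement
    varies between images -- the resolution of "randomly cropped with a
    stride of 25").  Pairs whose *label* patch contains no foreground
    (all zeros) are discarded; only fully-inside patches are kept.
    """
    input_img = np.asarray(input_img)
    label_img = np.asarray(label_img)
    if input_img.shape != label_img.shape:
        raise ValueError("input and label images must share shape")
    h, w = input_img.shape
    if size > min(h, w):
        raise ValueError("patch size exceeds image")
    if offset is None:
        rng = rng or np.random.default_rng(0)
        offset = (int(rng.integers(stride)), int(rng.integers(stride)))
    oi, oj = offset
    ins, labs, prov = [], [], []
    for i in range(oi, h - size + 1, stride):
        for j in range(oj, w - size + 1, stride):
            lab = label_img[i:i + size, j:j + size]
            if not lab.any():
                continue
            ins.append(input_img[i:i + size, j:j + size])
            labs.append(lab)
            prov.append((image_id, i, j))
    if not ins:
        empty = np.zeros((0, size, size), dtype=np.float32)
        return PatchDataset(empty, empty.copy(), [])
    return PatchDataset(np.stack(ins), np.stack(labs), prov)


class Denoiser:
    """The dense-skip-connection denoising network."""

    def __init__(self, spec: NetworkSpec, seed: int = 0,
                 dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k = spec.kernel_size
        self.low = nn.Conv2d(1, spec.low_level_filters, k, rng, dtype)
        self.dense: list[nn.Conv2d] = []
        c = spec.low_level_filters
        for _ in range(spec.n_blocks):
            for _ in range(spec.convs_per_block):
                self.dense.append(nn.Conv2d(c, spec.growth, k, rng, dtype))
                c += spec.growth
        self.bottleneck = nn.Conv2d(c, spec.bottleneck_filters, 1, rng, dtype)
        self.upscale = [nn.Conv2d(spec.bottleneck_filters,
                                  spec.bottleneck_filters, k, rng, dtype)
                        for _ in range(spec.upscale_stages)]
        self.recon = nn.Conv2d(spec.bottleneck_filters, 1, k, rng, dtype)
        self.normalization_constant: float | None = None
        self.trained = False
        self._acts: list[np.ndarray] = []

    # -- introspection -----------------------------------------------------
    @property
    def layers(self) -> list[nn.Conv2d]:
        return [self.low, *self.dense, self.bottleneck, *self.upscale,
                self.recon]

    def dense_input_channels(self) -> list[int]:
        """Channel count entering each in-block convolution, in order."""
        return [conv.c_in for conv in self.dense]

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """``x``: (N, H, W, 1) normalized intensities."""
        acts = []
        f = nn.relu(self.low.forward(x, cache))
        acts.append(f)
        feats = f
        for conv in self.dense:
            y = nn.relu(conv.forward(feats, cache))
            acts.append(y)
            feats = np.concatenate([feats, y], axis=-1)
        b = nn.relu(self.bottleneck.forward(feats, cache))
        acts.append(b)
        u = b
        for conv in self.upscale:
            u = nn.relu(conv.forward(u, cache))
            acts.append(u)
        out = self.recon.forward(u, cache)
        if cache:
            self._acts = acts
        return out

    def backward(self, dout: np.ndarray) -> None:
        acts = self._acts
        n_up = len(self.upscale)
        d = self.recon.backward(dout)
        for i, conv in enumerate(reversed(self.upscale)):
            a = acts[-(i + 1)]
            d = conv.backward(nn.relu_grad(d, a))
        b = acts[len(self.dense) + 1]
        dfeats = self.bottleneck.backward(nn.relu_grad(d, b))
        for i in range(len(self.dense) - 1, -1, -1):
            conv = self.dense[i]
            y = acts[i + 1]
            dy = dfeats[..., conv.c_in:]
            dprev = np.ascontiguousarray(dfeats[..., :conv.c_in])
            dprev += conv.backward(nn.relu_grad(dy, y))
            dfeats = dprev
        self.low.backward(nn.relu_grad(dfeats, acts[0]), need_dx=False)

    # -- parameters --------------------------------------------------------
    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def state_dict(self) -> dict:
        state = {"spec": self.spec.__dict__,
                 "normalization_constant": self.normalization_constant,
                 "trained": self.trained}
        for i, layer in enumerate(self.layers):
            state[f"W{i}"] = layer.W
            state[f"b{i}"] = layer.b
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            layer.W = np.asarray(state[f"W{i}"], dtype=self.dtype)
            layer.b = np.asarray(state[f"b{i}"], dtype=self.dtype)
        self.normalization_constant = state.get("normalization_constant")
        self.trained = bool(state.get("trained", True))


def build_model(spec: NetworkSpec, seed: int = 0,
                dtype=np.float32) -> Denoiser:
    """Fresh network with He-random weights and zero biases."""
    return Denoiser(spec, seed=seed, dtype=dtype)


def fit_normalization(dataset: PatchDataset,
                      percentile: float = 99.9) -> float:
    """Counts-to-unit normalization constant: high percentile of labels."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    c = float(np.percentile(dataset.labels, percentile))
    return c if c > 0 else 1.0


def train(model: Denoiser, dataset: PatchDataset, cfg: TrainConfig
          ) -> tuple[Denoiser, list[float]]:
    """Minibatch Adam training; one iteration = one batch.

    Inputs/labels are divided by the normalization constant (fitted from
    the labels when not supplied).  Returns the model (trained in place)
    and the per-iteration RMSE loss history, in normalized units.
    """
    if len(dataset) == 0:
        raise ValueError("cannot train on an empty dataset")
    norm = cfg.normalization_constant or fit_normalization(dataset)
    model.normalization_constant = norm
    x = (dataset.inputs / norm)[..., None].astype(model.dtype)
    t = (dataset.labels / norm)[..., None].astype(model.dtype)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.params, lr=cfg.learning_rate, beta1=cfg.momentum,
                  weight_decay=cfg.weight_decay)
    history: list[float] = []
    m = len(dataset)
    for _ in range(cfg.iterations):
        idx = rng.integers(0, m, size=cfg.batch_size)
        pred = model.forward(x[idx], cache=True)
        loss, dpred = nn.rmse_loss(pred, t[idx])
        model.backward(dpred)
        opt.step(model.grads)
        history.append(loss)
    model.trained = True
    return model, history


def denoise_image(model: Denoiser, image: CountImage | np.ndarray,
                  fraction: float | None = None) -> np.ndarray:
    """Denoise one count image; returns real-valued counts >= 0.

    The image is scale-corrected by its count fraction (taken from the
    ``CountImage`` metadata unless given), normalized, run through the
    network whole (the stride-1 architecture accepts any image size),
    un-normalized and clamped at zero.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained")
    if model.normalization_constant is None:
        raise RuntimeError("model carries no normalization constant")
    if isinstance(image, CountImage):
        arr = image.counts
        fraction = image.fraction if fraction is None else fraction
    else:
        arr = np.asarray(image)
        fraction = 1.0 if fraction is None else fraction
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    x = arr.astype(np.float32) / (fraction * model.normalization_constant)
    out = model.forward(x[None, ..., None], cache=False)[0, ..., 0]
    out = np.clip(out.astype(np.float64) * model.normalization_constant,
                  0.0, None)
    return out
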