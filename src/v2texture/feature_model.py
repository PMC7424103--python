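"""Configurable layered feature extractor with receptive-field arithmetic.

The extractor stacks the four computations of the classic convolutional
hierarchy: convolution (cross-correlation with zero padding), ReLU
rectification, overlapping max pooling, and local response normalization
(divisive normalization across a depth neighborhood of channels).  The
default layer order places normalization after pooling, following the
CaffeNet variant of AlexNet.  Weight sets can be user-provided, random
uniform in [-1, 1], or spatially shuffled versions of a trained set —
the two controls used to probe the role of learning versus architecture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "LayerSpec",
    "ArchitectureSpec",
    "WeightSet",
    "PopulationSelector",
    "gabor_weight_bank",
    "energy_coincidence_weights",
    "local_response_norm",
    "receptive_field_size",
    "init_weights",
    "run_network",
    "extract_population",
    "compute_response_tensor",
    "load_bundled_spec",
]

_LAYER_KINDS = ("conv", "relu", "maxpool", "lrn")


@dataclass(frozen=True)
class LayerSpec:
    """One layer: its kind and geometry parameters.

    conv: n_filters, kernel_side, stride, pad, n_input_channels.
    maxpool: window, stride.  lrn: k, alpha, beta, m (odd depth size).
    """

    name: str
    kind: str
    n_filters: int = 0
    kernel_side: int = 0
    stride: int = 1
    pad: int = 0
    n_input_channels: int = 0
    window: int = 0
    k: float = 2.0
    alpha: float = 1e-4
    beta: float = 0.75
    m: int = 5

    def __post_init__(self) -> None:
        if self.kind not in _LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.stride < 1:
            raise ValueError(f"layer {self.name}: stride must be >= 1")
        if self.kind == "conv" and (self.kernel_side < 1 or self.n_filters < 1):
            raise ValueError(f"layer {self.name}: conv needs kernel_side and n_filters >= 1")
        if self.kind == "maxpool" and self.window < 1:
            raise ValueError(f"layer {self.name}: maxpool needs window >= 1")
        if self.kind == "lrn" and (self.m < 1 or self.m % 2 == 0):
            raise ValueError(f"layer {self.name}: lrn neighborhood m must be odd and >= 1")


@dataclass
class ArchitectureSpec:
    """Ordered layer list with named tap points (each layer name is one)."""

    layers: list[LayerSpec]

    def __post_init__(self) -> None:
        names = [layer.name for layer in self.layers]
        if len(names) != len(set(names)):
            raise ValueError("layer names must be unique")

    def tap_points(self) -> list[str]:
        return [layer.name for layer in self.layers]

    def layers_until(self, tap_point: str) -> list[LayerSpec]:
        names = self.tap_points()
        if tap_point not in names:
            raise KeyError(f"unknown tap point {tap_point!r}; have {names}")
        return self.layers[: names.index(tap_point) + 1]

    def conv_layers(self) -> list[LayerSpec]:
        return [layer for layer in self.layers if layer.kind == "conv"]

    @property
    def input_channels(self) -> int:
        convs = self.conv_layers()
        if not convs:
            raise ValueError("spec has no conv layer")
        return convs[0].n_input_channels

    _KIND_FIELDS = {
        "conv": ("n_filters", "kernel_side", "stride", "pad", "n_input_channels"),
        "relu": (),
        "maxpool": ("window", "stride"),
        "lrn": ("k", "alpha", "beta", "m"),
    }

    def to_yaml(self, path: str | Path) -> None:
        doc = [
            {"name": layer.name, "kind": layer.kind}
            | {key: getattr(layer, key) for key in self._KIND_FIELDS[layer.kind]}
            for layer in self.layers
        ]
        Path(path).write_text(yaml.safe_dump({"layers": doc}, sort_keys=False))

    @classmethod
    def from_yaml(cls, source: str | Path) -> "ArchitectureSpec":
        text = Path(source).read_text()
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_dict(cls, doc: dict) -> "ArchitectureSpec":
        return cls(layers=[LayerSpec(**entry) for entry in doc["layers"]])


def load_bundled_spec(name: str) -> ArchitectureSpec:
    """Load one of the packaged geometries: ``alexnet_stride2``,
    ``alexnet_stride4`` or ``vgg16``."""
    ref = resources.files("v2texture").joinpath(f"specs/{name}.yaml")
    return ArchitectureSpec.from_dict(yaml.safe_load(ref.read_text()))


def receptive_field_size(spec: ArchitectureSpec, tap_point: str) -> tuple[int, int]:
    """Input-pixel side length of one unit's receptive field, and its jump.

    Standard recursion over conv and pool layers: rf <- rf + (window-1)*jump,
    jump <- jump*stride.  Rectification and normalization are pointwise in
    space and leave both unchanged; padding does not affect the side.
    """
    rf, jump = 1, 1
    for layer in spec.layers_until(tap_point):
        if layer.kind == "conv":
            rf += (layer.kernel_side - 1) * jump
            jump *= layer.stride
        elif layer.kind == "maxpool":
            rf += (layer.window - 1) * jump
            jump *= layer.stride
    return rf, jump


@dataclass
class WeightSet:
    """Per-conv-layer filter banks, with provenance of how they were made."""

    filters: dict[str, np.ndarray]
    mode: str = "provided"
    seed: int | None = None

    def validate_against(self, spec: ArchitectureSpec) -> None:
        for layer in spec.conv_layers():
            if layer.name not in self.filters:
                raise ValueError(f"missing filters for conv layer {layer.name!r}")
            shape = self.filters[layer.name].shape
            expected = (layer.n_filters, layer.n_input_channels, layer.kernel_side, layer.kernel_side)
            if shape != expected:
                raise ValueError(f"layer {layer.name}: filter shape {shape} != {expected}")

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {"mode": self.mode, "seed": self.seed, "layers": sorted(self.filters)}
        np.savez(path, __header__=json.dumps(header), **self.filters)

    @classmethod
    def load(cls, path: str | Path) -> "WeightSet":
        with np.load(path) as data:
            header = json.loads(str(data["__header__"]))
            filters = {name: data[name] for name in header["layers"]}
        return cls(filters=filters, mode=header["mode"], seed=header["seed"])


def init_weights(
    spec: ArchitectureSpec,
    mode: str = "random",
    seed: int = 0,
    base: WeightSet | None = None,
    cross_channel_shuffle: bool = False,
) -> WeightSet:
    """Build a weight set: ``random`` (i.i.d. uniform on [-1, 1]),
    ``shuffled`` (spatial permutation of a trained base, independently per
    filter and input channel), or ``provided`` (shape-checked passthrough).
    """
    if mode == "provided":
        if base is None:
            raise ValueError("provided mode requires a base WeightSet")
        base.validate_against(spec)
        return WeightSet(filters={k: v.copy() for k, v in base.filters.items()}, mode="provided")

    rng = np.random.default_rng(seed)
    filters: dict[str, np.ndarray] = {}
    if mode == "random":
        for layer in spec.conv_layers():
            shape = (layer.n_filters, layer.n_input_channels, layer.kernel_side, layer.kernel_side)
            filters[layer.name] = rng.uniform(-1.0, 1.0, size=shape)
        return WeightSet(filters=filters, mode="random", seed=seed)

    if mode == "shuffled":
        if base is None:
            raise ValueError("shuffled mode requires a base WeightSet")
        base.validate_against(spec)
        for layer in spec.conv_layers():
            w = base.filters[layer.name]
            nf, nc, kh, kw = w.shape
            out = np.empty_like(w)
            if cross_channel_shuffle:
                flat = w.reshape(nf, nc * kh * kw)
                for i in range(nf):
                    out[i] = flat[i, rng.permutation(nc * kh * kw)].reshape(nc, kh, kw)
            else:
                flat = w.reshape(nf, nc, kh * kw)
                for i in range(nf):
                    for c in range(nc):
                        out[i, c] = flat[i, c, rng.permutation(kh * kw)].reshape(kh, kw)
            filters[layer.name] = out
        return WeightSet(filters=filters, mode="shuffled", seed=seed)

    raise ValueError(f"unknown weight mode {mode!r}")


def gabor_weight_bank(
    orientations: int = 8,
    frequencies: Sequence[float] = (0.10, 0.20),
    kernel_side: int = 7,
    signed_pairs: bool = True,
) -> np.ndarray:
    """Oriented Gabor filter bank for a single-channel input.

    Filters are generated per (orientation, frequency, quadrature phase),
    each L1-normalized and zero-mean.  With ``signed_pairs`` every filter
    is followed by its negation, so that after rectification the pair
    carries the full-wave (absolute-value) response — the building block
    of an energy representation.  Returns (n_filters, 1, side, side).
    """
    grid = np.arange(kernel_side) - kernel_side // 2
    xx, yy = np.meshgrid(grid, grid)
    envelope = np.exp(-(xx**2 + yy**2) / (2 * (kernel_side / 3.5) ** 2))
    filters = []
    for i in range(orientations):
        theta = np.pi * i / orientations
        u = xx * np.cos(theta) + yy * np.sin(theta)
        for freq in frequencies:
            for phase in (0.0, np.pi / 2):
                f = envelope * np.cos(2 * np.pi * freq * u + phase)
                f -= f.mean()
                f /= np.abs(f).sum()
                filters.append(f)
                if signed_pairs:
                    filters.append(-f)
    return np.asarray(filters)[:, None, :, :]


def energy_coincidence_weights(
    orientations: int = 8,
    channels_per_orientation: int = 8,
    kernel_side: int = 5,
    surround_gain: float = 1.4,
) -> np.ndarray:
    """Second-stage filters detecting co-located oriented energy.

    One output per orientation: excitation at the kernel center across all
    of that orientation's first-stage channels (quadrature phases, signs
    and frequency bands), and divisively balancing inhibition spread over
    the spatial surround.  A unit therefore fires when energy across
    scales and phases coincides at one location above its local
    background — the signature of aligned phase structure in naturalistic
    textures, which spectrally matched noise lacks.  ``surround_gain``
    scales the inhibition; above 1 the unit behaves like a soft
    coincidence threshold.  Channel layout must match
    ``gabor_weight_bank`` (orientation-major).
    """
    n_in = orientations * channels_per_orientation
    w = np.zeros((orientations, n_in, kernel_side, kernel_side))
    center = kernel_side // 2
    surround = np.ones((kernel_side, kernel_side))
    surround[center, center] = 0.0
    surround /= surround.sum()
    for o in range(orientations):
        for c in range(channels_per_orientation):
            ch = o * channels_per_orientation + c
            w[o, ch, center, center] = 1.0
            w[o, ch] -= surround_gain * surround
    return w


def local_response_norm(
    maps: np.ndarray, k: float = 2.0, alpha: float = 1e-4, beta: float = 0.75, m: int = 5
) -> np.ndarray:
    """Divisive normalization across a depth neighborhood of ``m`` channels.

    b[i] = a[i] / (k + alpha * sum_{j in [i-m//2, i+m//2] clamped} a[j]^2)^beta
    applied at every spatial position; the channel sum is clamped at the
    edges of the channel range.
    """
    a = np.asarray(maps, dtype=np.float64)
    if a.ndim != 3:
        raise ValueError(f"expected (channels, H, W) maps, got shape {a.shape}")
    if np.any(a < 0):
        raise ValueError("local_response_norm expects nonnegative (rectified) inputs")
    if m < 1:
        raise ValueError("m must be >= 1")
    half = m // 2
    sq = a**2
    # clamped running sum over channels via padded cumulative sum
    csum = np.concatenate([np.zeros((1,) + a.shape[1:]), np.cumsum(sq, axis=0)], axis=0)
    n_ch = a.shape[0]
    lo = np.maximum(np.arange(n_ch) - half, 0)
    hi = np.minimum(np.arange(n_ch) + half, n_ch - 1)
    neighborhood = csum[hi + 1] - csum[lo]
    return a / (k + alpha * neighborhood) ** beta


def _conv_forward(x: np.ndarray, layer: LayerSpec, weights: np.ndarray) -> np.ndarray:
    if layer.pad:
        x = np.pad(x, ((0, 0), (layer.pad, layer.pad), (layer.pad, layer.pad)))
    kh = layer.kernel_side
    if x.shape[1] < kh or x.shape[2] < kh:
        raise ValueError(
            f"layer {layer.name!r}: padded input {x.shape[1:]} smaller than kernel {kh}"
        )
    windows = sliding_window_view(x, (kh, kh), axis=(1, 2))[:, :: layer.stride, :: layer.stride]
    return np.einsum("chwij,fcij->fhw", windows, weights, optimize=True)


def _pool_forward(x: np.ndarray, layer: LayerSpec) -> np.ndarray:
    w = layer.window
    if x.shape[1] < w or x.shape[2] < w:
        raise ValueError(f"layer {layer.name!r}: map {x.shape[1:]} smaller than window {w}")
    windows = sliding_window_view(x, (w, w), axis=(1, 2))[:, :: layer.stride, :: layer.stride]
    return windows.max(axis=(-2, -1))


def _forward(x: np.ndarray, layers: Sequence[LayerSpec], weights: WeightSet) -> np.ndarray:
    for layer in layers:
        if layer.kind == "conv":
            x = _conv_forward(x, layer, weights.filters[layer.name])
        elif layer.kind == "relu":
            x = np.maximum(x, 0.0)
        elif layer.kind == "maxpool":
            x = _pool_forward(x, layer)
        elif layer.kind == "lrn":
            x = local_response_norm(x, layer.k, layer.alpha, layer.beta, layer.m)
        if x.shape[1] < 1 or x.shape[2] < 1:
            raise ValueError(f"feature map vanished below 1x1 at layer {layer.name!r}")
    return x


def _to_channels(image: np.ndarray, n_channels: int) -> np.ndarray:
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] == n_channels:
        return arr
    if arr.shape[0] == 1:
        # grayscale stimuli replicated across the expected input channels
        return np.broadcast_to(arr, (n_channels,) + arr.shape[1:]).copy()
    raise ValueError(f"cannot map {arr.shape[0]}-channel input to {n_channels} channels")


def run_network(
    images: Sequence[np.ndarray],
    spec: ArchitectureSpec,
    weights: WeightSet,
    tap_point: str,
) -> np.ndarray:
    """Run the extractor on a batch of images up to ``tap_point``.

    Returns an array (n_images, n_channels, H, W) of feature maps at the
    tap point.  Grayscale images are replicated when the first conv layer
    declares more input channels.
    """
    weights.validate_against(spec)
    layers = spec.layers_until(tap_point)
    n_in = spec.input_channels
    outputs = [_forward(_to_channels(img, n_in), layers, weights) for img in images]
    return np.stack(outputs)


@dataclass(frozen=True)
class PopulationSelector:
    """Which units form the model population: a filter subset times a
    centered spatial neighborhood at a named tap point."""

    filter_indices: tuple[int, ...]
    spatial_neighborhood: int = 2
    tap_point: str = "norm2"

    def __post_init__(self) -> None:
        if self.spatial_neighborhood < 1:
            raise ValueError("spatial neighborhood side must be >= 1")

    @property
    def n_neurons(self) -> int:
        return len(self.filter_indices) * self.spatial_neighborhood**2


def extract_population(maps: np.ndarray, selector: PopulationSelector) -> np.ndarray:
    """Responses of (filter, spatial position) units to each image.

    For a map of side S and neighborhood side s, the rows/cols span offsets
    floor((S-s)/2) .. floor((S-s)/2)+s-1.  Neuron order is filter-major,
    then row, then column.  Returns (n_neurons, n_images).
    """
    maps = np.asarray(maps)
    if maps.ndim != 4:
        raise ValueError(f"expected (n_images, channels, H, W), got {maps.shape}")
    _, _, h, w = maps.shape
    s = selector.spatial_neighborhood
    if s > h or s > w:
        raise ValueError(f"neighborhood side {s} exceeds map side {min(h, w)}")
    r0, c0 = (h - s) // 2, (w - s) // 2
    patch = maps[:, list(selector.filter_indices), r0 : r0 + s, c0 : c0 + s]
    n_images = maps.shape[0]
    return patch.reshape(n_images, -1).T


def population_metadata(selector: PopulationSelector, map_side: int) -> list[tuple[int, int, int, str]]:
    """(filter, row, col, tap_point) for each neuron, in extraction order."""
    s = selector.spatial_neighborhood
    r0 = (map_side - s) // 2
    return [
        (f, r0 + r, r0 + c, selector.tap_point)
        for f in selector.filter_indices
        for r in range(s)
        for c in range(s)
    ]


def compute_response_tensor(ensemble, spec: ArchitectureSpec, weights: WeightSet, selector: PopulationSelector):
    """Run the network on a paired ensemble and package the population
    responses as a neuron x family x sample x stimulus-type tensor."""
    from .texture_sensitivity import ResponseTensor

    n_fam, n_samp = ensemble.n_families, ensemble.n_samples
    images, index = [], []
    for family_id, sample, kind, img in ensemble.iter_images():
        index.append((family_id, sample, 0 if kind == "naturalistic" else 1))
        images.append(img)
    maps = run_network(images, spec, weights, selector.tap_point)
    pop = extract_population(maps, selector)  # (neurons, images)

    responses = np.empty((pop.shape[0], n_fam, n_samp, 2))
    fam_ids = sorted({f for f, _, _ in index})
    fam_pos = {f: i for i, f in enumerate(fam_ids)}
    for col, (family_id, sample, stim) in enumerate(index):
        responses[:, fam_pos[family_id], sample, stim] = pop[:, col]
    meta = population_metadata(selector, maps.shape[-1])
    return ResponseTensor(responses=responses, neuron_meta=meta, tap_point=selector.tap_point)
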