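"""Synthetic texture families and planted model-neuron response tensors.

Naturalistic textures differ from spectrally matched noise only in their
higher-order statistics: both share the Fourier amplitude spectrum, but
textures carry aligned phase structure (edges, blobs, repetitive marks).
The generator here emulates exactly that contrast without a full joint
statistic matching procedure: oriented band-pass filtered Gaussian noise
is passed through a pointwise nonlinearity (sign-preserving squaring plus
soft thresholding), which concentrates energy into sparse, kurtotic
features, and the result is then spectrum-flattened back to the family's
reference amplitude spectrum.  A texture and its phase-randomized partner
therefore differ only in phase structure, and the difference is visible
in fourth-order statistics of oriented filter outputs.

The planted response tensor plays the complementary role: model-neuron
responses with an exactly known per-neuron, per-family modulation index,
so the downstream index computation and the three fitting procedures can
be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .texture_sensitivity import ModulationProfile, ResponseTensor

__all__ = [
    "SyntheticTextureParams",
    "PlantedResponseParams",
    "generate_texture_family",
    "generate_texture_set",
    "generate_response_tensor",
    "generate_planted_target",
]


@dataclass(frozen=True)
class SyntheticTextureParams:
    """Parameters of the texture-family generator.

    ``structure_strength`` in [0, 1] interpolates between pure (colored)
    Gaussian noise at 0 and fully structured, kurtotic texture at 1.
    """

    n_families: int = 15
    n_samples: int = 15
    image_side: int = 64
    structure_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.image_side < 8 or self.image_side % 2:
            raise ValueError("image_side must be even and >= 8")
        if not 0.0 <= self.structure_strength <= 1.0:
            raise ValueError("structure_strength must lie in [0, 1]")


@dataclass(frozen=True)
class PlantedResponseParams:
    """Parameters of the planted response-tensor generator.

    ``planted_modulation`` is the (n_neurons, n_families) matrix of target
    modulation indices, each strictly inside (-1, 1); with ``noise_sd`` = 0
    the family-mean responses reproduce it exactly.
    """

    n_neurons: int
    n_families: int
    n_samples: int
    planted_modulation: np.ndarray
    response_scale: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.planted_modulation, dtype=np.float64)
        if m.shape != (self.n_neurons, self.n_families):
            raise ValueError(
                f"planted_modulation shape {m.shape} != ({self.n_neurons}, {self.n_families})"
            )
        if not np.all(np.abs(m) < 1.0):
            raise ValueError("planted modulation values must lie strictly inside (-1, 1)")
        if not self.response_scale > 0:
            raise ValueError("response_scale must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "planted_modulation", m)


def _family_spectrum(side: int, family_rng: np.random.Generator) -> tuple[np.ndarray, float, float]:
    """Family-specific reference amplitude spectrum: 1/f radial falloff with
    an oriented Gaussian lobe.  Returns (amplitude, orientation, peak freq)."""
    theta = family_rng.uniform(0.0, np.pi)
    peak = family_rng.uniform(0.08, 0.2)  # cycles/pixel
    bandwidth = family_rng.uniform(0.4, 0.8)  # radians, angular

    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.fftfreq(side)[None, :]
    radius = np.hypot(fx, fy)
    angle = np.arctan2(fy, fx)

    with np.errstate(divide="ignore"):
        radial = np.where(radius > 0, 1.0 / np.maximum(radius, 1e-6), 0.0)
    lobe = np.exp(-((radius - peak) ** 2) / (2 * 0.05**2))
    # angular tuning, pi-periodic (real images have symmetric spectra)
    dtheta = np.angle(np.exp(2j * (angle - theta))) / 2.0
    angular = np.exp(-(dtheta**2) / (2 * bandwidth**2))
    amp = radial + 25.0 * lobe * angular
    amp[0, 0] = 0.0  # DC handled separately
    return amp, theta, peak


def _impose_spectrum(image: np.ndarray, amplitude: np.ndarray) -> np.ndarray:
    """Replace the amplitude spectrum of ``image`` by ``amplitude``, keeping
    its phases; the DC bin is zeroed (mean is set afterwards)."""
    spectrum = np.fft.fft2(image)
    mag = np.abs(spectrum)
    with np.errstate(invalid="ignore", divide="ignore"):
        phase_only = np.where(mag > 0, spectrum / mag, 1.0)
    out = np.fft.ifft2(amplitude * phase_only).real
    return out


def generate_texture_family(
    params: SyntheticTextureParams, family_id: int
) -> list[np.ndarray]:
    """Generate the naturalistic samples of one texture family.

    Each sample is a deterministic function of (seed, family_id, sample
    index); family-level properties (reference spectrum, orientation) are
    a function of (seed, family_id) alone, so samples share second-order
    statistics while differing in their random phase structure.
    """
    if family_id < 0 or family_id >= params.n_families:
        raise ValueError(f"family_id {family_id} outside [0, {params.n_families})")

    side = params.image_side
    family_rng = np.random.default_rng(np.random.SeedSequence([params.seed, family_id]))
    amplitude, _, _ = _family_spectrum(side, family_rng)
    threshold = family_rng.uniform(0.5, 1.5)

    images = []
    for s in range(params.n_samples):
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, family_id, s]))
        white = rng.standard_normal((side, side))
        base = _impose_spectrum(white, amplitude)
        base /= base.std()

        # Pointwise nonlinearity: sign-preserving squaring plus soft
        # thresholding.  Concentrates energy into sparse aligned features,
        # raising the kurtosis of oriented filter outputs.
        sparse = base * np.abs(base)
        shrunk = np.sign(sparse) * np.maximum(np.abs(sparse) - threshold, 0.0)
        structured = _impose_spectrum(shrunk, amplitude)
        if structured.std() > 0:
            structured /= structured.std()

        mix = (1.0 - params.structure_strength) * base + params.structure_strength * structured
        out = _impose_spectrum(mix, amplitude)
        out /= out.std()
        # place in a nominal [0, 1]-ish pixel range
        images.append(0.5 + 0.18 * out)
    return images


def generate_texture_set(params: SyntheticTextureParams) -> list[list[np.ndarray]]:
    """All families of a synthetic texture set, as nested image lists."""
    return [generate_texture_family(params, f) for f in range(params.n_families)]


def generate_response_tensor(params: PlantedResponseParams) -> "ResponseTensor":
    """Model-neuron responses with an exactly planted modulation structure.

    For neuron i and family f, the family-mean texture and noise responses
    are r_na = T(1+m)/2 and r_no = T(1-m)/2 with m the planted index and T
    a per-(neuron, family) positive total response, so (r_na - r_no) /
    (r_na + r_no) = m exactly.  Per-sample responses add Gaussian jitter of
    scale ``noise_sd`` truncated at zero (responses are post-rectification
    and hence nonnegative).
    """
    from .texture_sensitivity import ResponseTensor

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0x7E57]))
    m = params.planted_modulation
    n, f, s = params.n_neurons, params.n_families, params.n_samples

    total = params.response_scale * rng.uniform(0.8, 1.2, size=(n, f))
    r_na = total * (1.0 + m) / 2.0
    r_no = total * (1.0 - m) / 2.0
    means = np.stack([r_na, r_no], axis=-1)  # (n, f, 2)

    responses = np.repeat(means[:, :, None, :], s, axis=2)
    if params.noise_sd > 0:
        jitter = params.noise_sd * rng.standard_normal(size=(n, f, s, 2))
        responses = np.maximum(responses + jitter, 0.0)
    return ResponseTensor(responses=responses, tap_point="synthetic")


def generate_planted_target(profile: "ModulationProfile", subset: np.ndarray) -> np.ndarray:
    """Target vector realized exactly by a planted subset: the equally
    weighted mean of the subset's modulation rows."""
    idx = np.asarray(subset, dtype=int)
    if idx.size == 0:
        raise ValueError("subset must be nonempty")
    n = profile.M_matrix.shape[0]
    if idx.min() < 0 or idx.max() >= n:
        raise ValueError(f"subset indices must lie in [0, {n})")
    return profile.M_matrix[idx].mean(axis=0)
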