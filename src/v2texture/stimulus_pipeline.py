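"""Preparation of paired naturalistic/noise stimulus ensembles.

A texture experiment presents, for each texture family, naturalistic
samples alongside *spectrally matched noise*: images with the identical
Fourier amplitude spectrum but independently randomized phases, which
destroys the higher-order (beyond second-order) statistical structure.
This module builds such paired ensembles: phase randomization at native
resolution, block-average downsampling so model receptive fields cover a
comparable portion of the stimulus, and an affine contrast/luminance
normalization applied to every image before it is fed to the feature
model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ContrastNormParams",
    "FamilyRecord",
    "TextureEnsemble",
    "phase_randomize",
    "downsample",
    "contrast_normalize",
    "build_ensemble",
    "read_image",
    "write_ensemble",
]


@dataclass(frozen=True)
class ContrastNormParams:
    """Target contrast (standard deviation) and luminance (mean) of a stimulus.

    ``alpha`` is the desired pixel standard deviation, ``beta`` the desired
    mean; images are mapped affinely so both are met exactly.  The defaults
    (0.22, 0.5) place a mid-gray image comfortably inside the [0, 1] range.
    """

    alpha: float = 0.22
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must lie in (0, 1), got {self.beta}")


def _as_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if np.iscomplexobj(arr):
        raise ValueError("expected a real-valued image")
    return arr.astype(np.float64, copy=False)


def phase_randomize(image: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Return an image with the same amplitude spectrum but random phases.

    The 2-D DFT phases of all non-self-conjugate frequency pairs are
    replaced by i.i.d. uniform draws on [0, 2pi), with Hermitian symmetry
    enforced so the output is real.  Self-conjugate bins (DC and Nyquist
    rows/columns' corners) keep their original real values, which preserves
    the image mean exactly.
    """
    arr = _as_image(image)
    if min(arr.shape) < 2:
        raise ValueError("image sides must be at least 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    spectrum = np.fft.fft2(arr)
    amplitude = np.abs(spectrum)

    # Antisymmetrized uniform phases: phi[k] - phi[-k] is uniform mod 2*pi,
    # odd under k -> -k, and exactly zero at self-conjugate bins.
    phases = rng.uniform(0.0, 2.0 * np.pi, size=arr.shape)
    phases_neg = np.roll(phases[::-1, ::-1], shift=(1, 1), axis=(0, 1))
    randomized = amplitude * np.exp(1j * (phases - phases_neg))

    n0, n1 = arr.shape
    rows = np.arange(n0)
    cols = np.arange(n1)
    self_conj = ((2 * rows[:, None]) % n0 == 0) & ((2 * cols[None, :]) % n1 == 0)
    randomized[self_conj] = spectrum[self_conj]

    return np.fft.ifft2(randomized).real


def downsample(image: np.ndarray, factor: int, method: str = "block") -> np.ndarray:
    """Reduce image resolution by an integer power-of-two factor.

    ``block`` (default) applies repeated 2x2 block averaging, which is
    anti-aliasing and mean-preserving.  ``stride`` takes every ``factor``-th
    pixel instead.
    """
    arr = _as_image(image)
    if factor < 1 or (factor & (factor - 1)) != 0:
        raise ValueError(f"factor must be a positive power of 2, got {factor}")
    if any(side % factor for side in arr.shape):
        raise ValueError(f"image sides {arr.shape} not divisible by factor {factor}")
    if method == "stride":
        return arr[::factor, ::factor].copy()
    if method != "block":
        raise ValueError(f"unknown downsampling method {method!r}")
    out = arr
    remaining = factor
    while remaining > 1:
        h, w = out.shape
        out = out.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))
        remaining //= 2
    return out.copy() if out is arr else out


def contrast_normalize(image: np.ndarray, params: ContrastNormParams = ContrastNormParams()) -> np.ndarray:
    """Affinely map an image to mean ``beta`` and population SD ``alpha``."""
    arr = _as_image(image)
    luminance = arr.mean()
    contrast = arr.std()  # population (divide-by-N) standard deviation
    if contrast == 0:
        raise ValueError("constant image: contrast is zero, normalization undefined")
    return params.alpha * (arr - luminance) / contrast + params.beta


@dataclass
class FamilyRecord:
    """One texture family: paired (naturalistic, noise) images per sample."""

    family_id: int
    samples: list[tuple[np.ndarray, np.ndarray]]


@dataclass
class TextureEnsemble:
    """Paired naturalistic/noise image sets organized by family and sample."""

    families: list[FamilyRecord]
    image_side: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_samples(self) -> int:
        return len(self.families[0].samples) if self.families else 0

    def iter_images(self) -> Iterator[tuple[int, int, str, np.ndarray]]:
        """Yield (family_id, sample_index, stimulus_type, image) tuples."""
        for fam in self.families:
            for s, (tex, noise) in enumerate(fam.samples):
                yield fam.family_id, s, "naturalistic", tex
                yield fam.family_id, s, "noise", noise

    def validate(self) -> None:
        counts = {len(fam.samples) for fam in self.families}
        if len(counts) > 1:
            raise ValueError(f"families have unequal sample counts: {sorted(counts)}")
        for fam in self.families:
            for s, (tex, noise) in enumerate(fam.samples):
                if tex.shape != noise.shape:
                    raise ValueError(
                        f"family {fam.family_id} sample {s}: texture/noise shape mismatch"
                    )
                if tex.shape != (self.image_side, self.image_side):
                    raise ValueError(
                        f"family {fam.family_id} sample {s}: side {tex.shape} != {self.image_side}"
                    )


def build_ensemble(
    texture_images: Sequence[Sequence[np.ndarray]],
    factor: int = 4,
    params: ContrastNormParams = ContrastNormParams(),
    seed: int = 0,
    method: str = "block",
) -> TextureEnsemble:
    """Assemble a paired texture/noise ensemble from raw family image lists.

    For each naturalistic image the noise partner is generated by phase
    randomization at the native resolution; both are then downsampled by
    ``factor`` and contrast normalized.  The phase-randomization stream is
    keyed by (seed, family, sample) so the ensemble is reproducible and
    insensitive to iteration order.
    """
    if not texture_images or any(len(fam) == 0 for fam in texture_images):
        raise ValueError("texture_images must contain at least one family with images")
    sample_counts = {len(fam) for fam in texture_images}
    if len(sample_counts) > 1:
        raise ValueError(f"families must have equal sample counts, got {sorted(sample_counts)}")

    families: list[FamilyRecord] = []
    for f, fam_images in enumerate(texture_images):
        samples = []
        for s, img in enumerate(fam_images):
            try:
                rng = np.random.default_rng(np.random.SeedSequence([seed, f, s]))
                noise = phase_randomize(img, rng)
                tex_out = contrast_normalize(downsample(img, factor, method), params)
                noise_out = contrast_normalize(downsample(noise, factor, method), params)
            except ValueError as exc:
                raise ValueError(f"family {f}, sample {s}: {exc}") from exc
            samples.append((tex_out, noise_out))
        families.append(FamilyRecord(family_id=f, samples=samples))

    side = families[0].samples[0][0].shape[0]
    ensemble = TextureEnsemble(
        families=families,
        image_side=side,
        provenance={
            "downsample_factor": factor,
            "downsample_method": method,
            "alpha": params.alpha,
            "beta": params.beta,
            "seed": seed,
        },
    )
    ensemble.validate()
    return ensemble


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale PNG/TIFF image; 8-bit inputs are rescaled to [0, 1]."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("F" if im.mode in ("F", "I") else "L"), dtype=np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr


def write_ensemble(ensemble: TextureEnsemble, out_dir: str | Path) -> Path:
    """Write an ensemble as ``family_<f>/sample_<s>_{tex|noise}.png`` + manifest."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"provenance": ensemble.provenance, "images": []}
    for family_id, s, kind, img in ensemble.iter_images():
        fam_dir = out / f"family_{family_id}"
        fam_dir.mkdir(exist_ok=True)
        tag = "tex" if kind == "naturalistic" else "noise"
        path = fam_dir / f"sample_{s}_{tag}.png"
        data = np.clip(img, 0.0, 1.0)
        Image.fromarray((data * 255).round().astype(np.uint8)).save(path)
        manifest["images"].append(
            {"family": family_id, "sample": s, "type": kind, "path": str(path.relative_to(out))}
        )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
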