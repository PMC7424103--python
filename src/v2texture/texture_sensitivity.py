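"""Modulation indices: the normalized differential response to textures.

The modulation index of a neuron for a texture family is

    M = (r_na - r_no) / (r_na + r_no)

where r_na and r_no are its mean responses to the family's naturalistic
samples and to their spectrally matched noise partners.  M > 0 means the
neuron responds more to naturalistic structure; a V2-like population has
mostly positive indices while a V1-like population centers near zero.
This module computes per-neuron per-family index matrices from response
tensors, filters out neurons for which the index is undefined, and
provides random-population summaries and a permutation null band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ResponseTensor",
    "ModulationProfile",
    "RandomPopulationSummary",
    "modulation_index",
    "modulation_matrix",
    "filter_valid_neurons",
    "population_mean_modulation",
    "sample_random_populations",
    "null_modulation_distribution",
]

NATURALISTIC, NOISE = 0, 1


@dataclass
class ResponseTensor:
    """Model-neuron responses: (neuron, family, sample, stimulus type).

    The last axis indexes stimulus type: 0 = naturalistic, 1 = noise.
    Responses from post-rectification tap points are nonnegative.
    """

    responses: np.ndarray
    neuron_meta: list | None = None
    tap_point: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.responses, dtype=np.float64)
        if arr.ndim != 4 or arr.shape[-1] != 2:
            raise ValueError(
                f"responses must be (neuron, family, sample, 2), got {arr.shape}"
            )
        if np.any(~np.isfinite(arr)):
            raise ValueError("responses contain non-finite entries")
        self.responses = arr

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_families(self) -> int:
        return self.responses.shape[1]

    @property
    def n_samples(self) -> int:
        return self.responses.shape[2]

    @property
    def naturalistic(self) -> np.ndarray:
        return self.responses[..., NATURALISTIC]

    @property
    def noise(self) -> np.ndarray:
        return self.responses[..., NOISE]

    def subset_samples(self, sample_sets: list[np.ndarray]) -> "ResponseTensor":
        """Restrict to per-family sample subsets of equal size (for CV folds)."""
        if len(sample_sets) != self.n_families:
            raise ValueError("need one sample set per family")
        sizes = {len(s) for s in sample_sets}
        if len(sizes) != 1:
            raise ValueError("sample subsets must have equal sizes across families")
        picked = np.stack(
            [self.responses[:, f, np.asarray(idx, dtype=int), :] for f, idx in enumerate(sample_sets)],
            axis=1,
        )
        return ResponseTensor(responses=picked, neuron_meta=self.neuron_meta, tap_point=self.tap_point)


@dataclass
class ModulationProfile:
    """Per-neuron, per-family modulation indices plus a validity mask.

    ``M_matrix`` is the matrix whose columns a population fit combines;
    invalid neurons (undefined index for some family) carry NaN rows.
    """

    M_matrix: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.M_matrix = np.asarray(self.M_matrix, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.M_matrix.ndim != 2:
            raise ValueError("M_matrix must be 2-D (neuron x family)")
        if self.valid_mask.shape != (self.M_matrix.shape[0],):
            raise ValueError("valid_mask must have one flag per neuron")

    @property
    def n_families(self) -> int:
        return self.M_matrix.shape[1]

    def to_csv(self, path: str | Path) -> None:
        n, f = self.M_matrix.shape
        frame = pd.DataFrame(
            {
                "neuron": np.repeat(np.arange(n), f),
                "family": np.tile(np.arange(f), n),
                "modulation_index": self.M_matrix.ravel(),
                "valid": np.repeat(self.valid_mask, f),
            }
        )
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ModulationProfile":
        frame = pd.read_csv(path)
        matrix = frame.pivot(index="neuron", columns="family", values="modulation_index")
        valid = frame.groupby("neuron")["valid"].first().to_numpy(dtype=bool)
        return cls(M_matrix=matrix.to_numpy(), valid_mask=valid)


def modulation_index(r_na, r_no):
    """(r_na - r_no) / (r_na + r_no), elementwise; undefined when the sum
    is not positive."""
    r_na = np.asarray(r_na, dtype=np.float64)
    r_no = np.asarray(r_no, dtype=np.float64)
    total = r_na + r_no
    if np.any(total <= 0):
        raise ValueError("modulation index undefined: r_na + r_no must be positive")
    out = (r_na - r_no) / total
    return float(out) if out.ndim == 0 else out


def modulation_matrix(tensor: ResponseTensor, per_sample: bool = False) -> ModulationProfile:
    """Per-neuron, per-family modulation indices from a response tensor.

    By default responses are averaged over a family's samples before the
    index is formed (stabilizing the ratio); ``per_sample=True`` instead
    averages per-sample indices.  Neurons whose index is undefined for any
    family (the family-summed response is not positive) are flagged invalid
    rather than raising.
    """
    if per_sample:
        total = tensor.naturalistic + tensor.noise  # (n, f, s)
        valid = np.all(total > 0, axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(total > 0, (tensor.naturalistic - tensor.noise) / total, np.nan)
        matrix = m.mean(axis=2)
    else:
        r_na = tensor.naturalistic.mean(axis=2)
        r_no = tensor.noise.mean(axis=2)
        total = r_na + r_no
        valid = np.all(total > 0, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            matrix = np.where(total > 0, (r_na - r_no) / total, np.nan)
    matrix = np.where(valid[:, None], matrix, np.nan)
    return ModulationProfile(M_matrix=matrix, valid_mask=valid)


def filter_valid_neurons(profile: ModulationProfile) -> np.ndarray:
    """Indices of neurons with a defined modulation index for every family."""
    return np.flatnonzero(profile.valid_mask)


def population_mean_modulation(profile: ModulationProfile, indices) -> np.ndarray:
    """Equally weighted mean modulation per family over the given neurons."""
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("cannot average an empty neuron set")
    if not profile.valid_mask[idx].all():
        raise ValueError("selection includes invalid neurons")
    return profile.M_matrix[idx].mean(axis=0)


@dataclass
class RandomPopulationSummary:
    """Summary of repeated random population draws.

    ``mean_modulation`` averages the per-family population mean over all
    repeats; ``per_repeat`` holds each repeat's per-family means;
    ``positive_fraction`` is the fraction of drawn neurons (pooled over
    repeats) whose family-averaged modulation index is positive.
    """

    mean_modulation: np.ndarray
    per_repeat: np.ndarray
    positive_fraction: float
    size: int
    n_repeats: int
    seed: int


def sample_random_populations(
    profile: ModulationProfile, size: int, n_repeats: int = 10_000, seed: int = 0
) -> RandomPopulationSummary:
    """Mean modulation of randomly drawn populations of ``size`` neurons.

    Each repeat draws ``size`` valid neurons without replacement and
    averages their modulation rows; the summary reports the across-repeat
    average per family and the fraction of drawn neurons with a positive
    (family-averaged) index.
    """
    valid = filter_valid_neurons(profile)
    if size < 1 or size > valid.size:
        raise ValueError(f"population size {size} outside [1, {valid.size}]")
    rng = np.random.default_rng(seed)
    rows = profile.M_matrix[valid]
    neuron_means = rows.mean(axis=1)

    per_repeat = np.empty((n_repeats, profile.n_families))
    positive = 0
    for r in range(n_repeats):
        pick = rng.choice(valid.size, size=size, replace=False)
        per_repeat[r] = rows[pick].mean(axis=0)
        positive += int(np.count_nonzero(neuron_means[pick] > 0))
    return RandomPopulationSummary(
        mean_modulation=per_repeat.mean(axis=0),
        per_repeat=per_repeat,
        positive_fraction=positive / (n_repeats * size),
        size=size,
        n_repeats=n_repeats,
        seed=seed,
    )


def null_modulation_distribution(
    tensor: ResponseTensor, n_perm: int = 1000, seed: int = 0
) -> np.ndarray:
    """Per-family (2.5th, 97.5th) percentile band of mean modulation under
    random texture/noise label exchange.

    Each permutation shuffles the 2*n_samples responses within every
    (neuron, family) cell across the texture/noise split, recomputes the
    family-mean modulation over valid neurons, and the band is taken over
    permutations.  Returns an (n_families, 2) array.
    """
    if tensor.n_samples < 2:
        raise ValueError("need at least 2 samples per family")
    if n_perm < 40:
        warnings.warn("fewer than 40 permutations: percentile band is unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    n, f, s = tensor.n_neurons, tensor.n_families, tensor.n_samples
    pooled = tensor.responses.reshape(n, f, 2 * s)

    bands = np.empty((n_perm, f))
    for p in range(n_perm):
        order = np.argsort(rng.random((n, f, 2 * s)), axis=-1)
        shuffled = np.take_along_axis(pooled, order, axis=-1)
        r_na = shuffled[..., :s].mean(axis=-1)
        r_no = shuffled[..., s:].mean(axis=-1)
        total = r_na + r_no
        valid = np.all(total > 0, axis=1)
        if not valid.any():
            bands[p] = np.nan
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            m = (r_na - r_no) / total
        bands[p] = m[valid].mean(axis=0)
    return np.stack(
        [np.nanpercentile(bands, 2.5, axis=0), np.nanpercentile(bands, 97.5, axis=0)], axis=1
    )
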