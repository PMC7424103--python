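"""Cross-validation schemes and end-to-end pipeline orchestration.

Generalization of a population fit is assessed two ways.  Leave-one-group-
out: each family's samples are partitioned into groups (nominally 15
images per group), every (family, group) pair is one data point, and each
fold refits the selection with one point held out and predicts that
point's mean modulation index.  Leave-family-out: the fit sees all but
one family's column and must predict the held-out family — a much harder
extrapolation, since nothing about that family's statistics enters the
fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data, stimulus_pipeline, feature_model
from .texture_sensitivity import (
    ModulationProfile,
    ResponseTensor,
    modulation_matrix,
    population_mean_modulation,
)
from .subset_fitting import (
    FitResult,
    euclidean_error,
    explained_variance,
    full_population_weights,
    greedy_subset,
    regularized_subset,
    spearman_correlation,
)

__all__ = [
    "CVPlan",
    "CVResult",
    "PipelineConfig",
    "StructuredVsRandomOutcome",
    "structured_vs_random_replicate",
    "make_cv_plan",
    "cross_validate",
    "leave_family_out",
    "run_pipeline",
]


@dataclass
class CVPlan:
    """Partition of (family, sample) space into held-out data points."""

    points: list[tuple[int, np.ndarray]]
    folds: list[int]
    group_size: int

    @property
    def n_points(self) -> int:
        return len(self.points)

    def validate(self, n_families: int, samples_per_family: int) -> None:
        seen: dict[int, set[int]] = {f: set() for f in range(n_families)}
        for family, samples in self.points:
            samples = set(int(s) for s in samples)
            if seen[family] & samples:
                raise ValueError(f"family {family}: samples assigned to multiple points")
            seen[family] |= samples
        for f, samples in seen.items():
            if samples != set(range(samples_per_family)):
                raise ValueError(f"family {f}: points do not cover all samples")
        if sorted(self.folds) != list(range(self.n_points)):
            raise ValueError("folds must hold out every point exactly once")


def make_cv_plan(
    n_families: int, samples_per_family: int, group_size: int = 15, seed: int = 0
) -> CVPlan:
    """Randomly partition each family's samples into groups of ``group_size``.

    Every group is one data point and one fold holds out exactly one point,
    so n_families * samples_per_family / group_size folds result.
    """
    if samples_per_family % group_size:
        raise ValueError(
            f"samples_per_family={samples_per_family} not divisible by group_size={group_size}"
        )
    rng = np.random.default_rng(seed)
    points: list[tuple[int, np.ndarray]] = []
    for f in range(n_families):
        order = rng.permutation(samples_per_family)
        for g in range(samples_per_family // group_size):
            points.append((f, np.sort(order[g * group_size : (g + 1) * group_size])))
    return CVPlan(points=points, folds=list(range(len(points))), group_size=group_size)


def _profile_from_sample_sets(
    tensor: ResponseTensor, sample_sets: list[np.ndarray]
) -> ModulationProfile:
    """Modulation profile with per-family sample subsets (possibly of
    unequal sizes, as in a training split)."""
    n, f = tensor.n_neurons, tensor.n_families
    r_na = np.empty((n, f))
    r_no = np.empty((n, f))
    for fam, idx in enumerate(sample_sets):
        idx = np.asarray(idx, dtype=int)
        r_na[:, fam] = tensor.naturalistic[:, fam, idx].mean(axis=1)
        r_no[:, fam] = tensor.noise[:, fam, idx].mean(axis=1)
    total = r_na + r_no
    valid = np.all(total > 0, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = np.where(total > 0, (r_na - r_no) / total, np.nan)
    matrix = np.where(valid[:, None], matrix, np.nan)
    return ModulationProfile(M_matrix=matrix, valid_mask=valid)


_FITTERS = {
    "greedy": lambda profile, target, k, lam: greedy_subset(profile, target, k),
    "full_population": lambda profile, target, k, lam: full_population_weights(profile, target),
    "regularized": lambda profile, target, k, lam: regularized_subset(profile, target, lam=lam, k=k),
}


def _fit(profile: ModulationProfile, target, method: str, k: int, lam: float) -> FitResult:
    if method not in _FITTERS:
        raise ValueError(f"unknown fit method {method!r}; have {sorted(_FITTERS)}")
    return _FITTERS[method](profile, target, k, lam)


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation outcome."""

    fold_train_errors: np.ndarray
    fold_test_errors: np.ndarray
    fold_predictions: np.ndarray
    fold_families: np.ndarray
    per_family_prediction: np.ndarray
    mean_train_error: float
    mean_test_error: float
    test_error: float
    spearman: float
    r_squared: float
    n_skipped: int


def cross_validate(
    tensor: ResponseTensor,
    target,
    plan: CVPlan,
    method: str = "greedy",
    k: int = 103,
    lam: float = 0.8,
) -> CVResult:
    """Leave-one-group-out evaluation of a fitting procedure.

    Each fold refits on all points but one, then predicts the held-out
    point's population mean modulation from the held-out samples alone;
    the fold's test error is the absolute deviation from the target entry
    of that point's family.  Folds whose held-out indices are undefined
    for the fitted population are skipped with a warning.
    """
    target = np.asarray(target, dtype=np.float64)
    plan.validate(tensor.n_families, tensor.n_samples)
    all_samples = [np.arange(tensor.n_samples) for _ in range(tensor.n_families)]

    train_errs, test_errs, preds, fams = [], [], [], []
    skipped = 0
    for fold in plan.folds:
        fam_h, idx_h = plan.points[fold]
        train_sets = [s.copy() for s in all_samples]
        train_sets[fam_h] = np.setdiff1d(train_sets[fam_h], idx_h)
        profile = _profile_from_sample_sets(tensor, train_sets)
        try:
            fit = _fit(profile, target, method, k, lam)
        except ValueError as exc:
            warnings.warn(f"fold {fold}: fit failed ({exc}); skipping", stacklevel=2)
            skipped += 1
            continue

        active = fit.weights > 0
        r_na = tensor.naturalistic[active][:, fam_h, idx_h].mean(axis=1)
        r_no = tensor.noise[active][:, fam_h, idx_h].mean(axis=1)
        total = r_na + r_no
        if np.any(total <= 0):
            warnings.warn(
                f"fold {fold}: undefined held-out modulation index; skipping", stacklevel=2
            )
            skipped += 1
            continue
        held_index = (r_na - r_no) / total
        pred = float(held_index @ fit.weights[active])

        train_errs.append(fit.train_error)
        test_errs.append(abs(pred - target[fam_h]))
        preds.append(pred)
        fams.append(fam_h)

    if not preds:
        raise ValueError("all folds skipped: cannot aggregate")
    preds_arr = np.asarray(preds)
    fams_arr = np.asarray(fams)
    per_family = np.full(tensor.n_families, np.nan)
    for f in range(tensor.n_families):
        mask = fams_arr == f
        if mask.any():
            per_family[f] = preds_arr[mask].mean()

    complete = ~np.isnan(per_family)
    test_error = euclidean_error(per_family[complete], target[complete])
    try:
        rho = spearman_correlation(per_family[complete], target[complete])
    except ValueError:
        rho = float("nan")
    try:
        r2 = explained_variance(per_family[complete], target[complete])
    except ValueError:
        r2 = float("nan")

    return CVResult(
        fold_train_errors=np.asarray(train_errs),
        fold_test_errors=np.asarray(test_errs),
        fold_predictions=preds_arr,
        fold_families=fams_arr,
        per_family_prediction=per_family,
        mean_train_error=float(np.mean(train_errs)),
        mean_test_error=float(np.mean(test_errs)),
        test_error=test_error,
        spearman=rho,
        r_squared=r2,
        n_skipped=skipped,
    )


@dataclass
class FamilyHoldoutResult:
    per_family_prediction: np.ndarray
    per_family_abs_error: np.ndarray
    test_error: float
    spearman: float


def leave_family_out(
    tensor: ResponseTensor, target, method: str = "greedy", k: int = 103, lam: float = 0.8
) -> FamilyHoldoutResult:
    """Fit on all-but-one family's columns; predict the held-out family.

    The predictor for the held-out family is the fitted population's
    (weighted) mean of that family's modulation column, computed from all
    of its samples.
    """
    target = np.asarray(target, dtype=np.float64)
    n_fam = tensor.n_families
    if n_fam < 2:
        raise ValueError("leave-family-out requires at least 2 families")
    profile = modulation_matrix(tensor)

    preds = np.empty(n_fam)
    for f in range(n_fam):
        keep = [c for c in range(n_fam) if c != f]
        sub = ModulationProfile(M_matrix=profile.M_matrix[:, keep], valid_mask=profile.valid_mask)
        fit = _fit(sub, target[keep], method, k, lam)
        preds[f] = float(fit.predict(profile.M_matrix[:, [f]])[0])

    abs_err = np.abs(preds - target)
    try:
        rho = spearman_correlation(preds, target)
    except ValueError:
        rho = float("nan")
    return FamilyHoldoutResult(
        per_family_prediction=preds,
        per_family_abs_error=abs_err,
        test_error=euclidean_error(preds, target),
        spearman=rho,
    )


@dataclass
class StructuredVsRandomOutcome:
    """One replicate of the trained-like vs random second-stage comparison."""

    structured_mean_modulation: float
    random_mean_modulation: float
    structured_test_error: float
    random_test_error: float

    @property
    def structured_wins(self) -> bool:
        return (
            self.structured_mean_modulation > self.random_mean_modulation
            and self.structured_test_error < self.random_test_error
        )


def structured_vs_random_replicate(
    seed: int,
    n_families: int = 10,
    n_samples: int = 6,
    n_target_samples: int = 10,
    image_side: int = 36,
    k: int = 30,
) -> StructuredVsRandomOutcome:
    """Does a structure-sensitive second stage beat random second-stage weights?

    A two-stage feature model (oriented Gabor bank, rectification, pooling;
    then energy-coincidence second-stage filters, rectification, pooling,
    normalization) is compared against the same model with uniform random
    second-stage weights.  The target modulation vector is computed from an
    independent-sample run of the structured model — standing in for data
    recorded from a texture-sensitive neural population.  Each condition is
    fitted by greedy subset selection on one sample set and scored on a
    disjoint held-out sample set, so spurious sample-noise diversity cannot
    masquerade as fit quality.  Returns the per-condition mean modulation
    indices and held-out fit errors.
    """
    from .subset_fitting import euclidean_error, greedy_subset
    from .texture_sensitivity import filter_valid_neurons

    spec = feature_model.ArchitectureSpec(
        layers=[
            feature_model.LayerSpec(
                name="conv1", kind="conv", n_filters=64, kernel_side=7, stride=1, pad=0, n_input_channels=1
            ),
            feature_model.LayerSpec(name="relu1", kind="relu"),
            feature_model.LayerSpec(name="pool1", kind="maxpool", window=2, stride=2),
            feature_model.LayerSpec(
                name="conv2", kind="conv", n_filters=8, kernel_side=5, stride=1, pad=0, n_input_channels=64
            ),
            feature_model.LayerSpec(name="relu2", kind="relu"),
            feature_model.LayerSpec(name="pool2", kind="maxpool", window=3, stride=2),
            feature_model.LayerSpec(name="norm2", kind="lrn"),
        ]
    )
    selector = feature_model.PopulationSelector(
        filter_indices=tuple(range(8)), spatial_neighborhood=4, tap_point="norm2"
    )
    conv1 = feature_model.gabor_weight_bank()
    structured_conv2 = feature_model.energy_coincidence_weights()
    random_conv2 = np.random.default_rng(seed + 999).uniform(-1.0, 1.0, structured_conv2.shape)

    def tensor_for(sample_offset: int, n: int, conv2: np.ndarray):
        params = synthetic_data.SyntheticTextureParams(
            n_families=n_families,
            n_samples=sample_offset + n,
            image_side=image_side,
            structure_strength=1.0,
            seed=seed,
        )
        images = [
            synthetic_data.generate_texture_family(params, f)[sample_offset:]
            for f in range(n_families)
        ]
        ensemble = stimulus_pipeline.build_ensemble(images, factor=1, seed=seed + sample_offset)
        weights = feature_model.WeightSet(
            filters={"conv1": conv1, "conv2": conv2}, mode="provided"
        )
        return feature_model.compute_response_tensor(ensemble, spec, weights, selector)

    # "recorded data": the structured system probed with independent samples
    data_tensor = tensor_for(2 * n_samples, n_target_samples, structured_conv2)
    data_profile = modulation_matrix(data_tensor)
    target = np.nanmean(
        data_profile.M_matrix[filter_valid_neurons(data_profile)], axis=0
    )

    results = {}
    for name, conv2 in (("structured", structured_conv2), ("random", random_conv2)):
        train = modulation_matrix(tensor_for(0, n_samples, conv2))
        test = modulation_matrix(tensor_for(n_samples, n_samples, conv2))
        valid = filter_valid_neurons(train)
        mean_mod = float(np.nanmean(train.M_matrix[valid]))
        fit = greedy_subset(train, target, k=min(k, valid.size))
        held_out = np.nanmean(test.M_matrix[np.asarray(fit.selected_indices)], axis=0)
        results[name] = (mean_mod, euclidean_error(held_out, target))

    return StructuredVsRandomOutcome(
        structured_mean_modulation=results["structured"][0],
        random_mean_modulation=results["random"][0],
        structured_test_error=results["structured"][1],
        random_test_error=results["random"][1],
    )


@dataclass
class PipelineConfig:
    """Full configuration of an end-to-end synthetic run."""

    n_families: int = 15
    n_samples: int = 15
    image_side: int = 64
    structure_strength: float = 1.0
    downsample_factor: int = 1
    alpha: float = 0.22
    beta: float = 0.5
    architecture: str = "alexnet_stride2"  # bundled name or YAML path
    weight_mode: str = "random"
    weights_path: str | None = None
    tap_points: list[str] = field(default_factory=lambda: ["norm2"])
    filter_indices: list[int] | None = None
    spatial_neighborhood: int = 2
    methods: list[str] = field(default_factory=lambda: ["greedy", "full_population", "regularized"])
    k: int = 103
    lam: float = 0.8
    target_path: str | None = None  # CSV with one mean modulation per family
    cv_scheme: str = "none"  # none | leave_group_out | leave_family_out
    cv_group_size: int | None = None
    out_dir: str = "pipeline_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _load_architecture(name_or_path: str) -> feature_model.ArchitectureSpec:
    if Path(name_or_path).exists():
        return feature_model.ArchitectureSpec.from_yaml(name_or_path)
    return feature_model.load_bundled_spec(name_or_path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Stimuli -> features -> modulation -> fits (-> CV), with reports.

    Returns the summary dictionary and writes CSV tables, a JSON summary,
    and bar/line plots under ``config.out_dir``.  Fully reproducible from
    (config, seed).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tex_params = synthetic_data.SyntheticTextureParams(
        n_families=config.n_families,
        n_samples=config.n_samples,
        image_side=config.image_side,
        structure_strength=config.structure_strength,
        seed=config.seed,
    )
    images = synthetic_data.generate_texture_set(tex_params)
    ensemble = stimulus_pipeline.build_ensemble(
        images,
        factor=config.downsample_factor,
        params=stimulus_pipeline.ContrastNormParams(config.alpha, config.beta),
        seed=config.seed,
    )

    spec = _load_architecture(config.architecture)
    if config.weight_mode == "provided":
        if not config.weights_path:
            raise ValueError("weight_mode 'provided' requires weights_path")
        base = feature_model.WeightSet.load(config.weights_path)
        weights = feature_model.init_weights(spec, "provided", base=base)
    else:
        weights = feature_model.init_weights(spec, config.weight_mode, seed=config.seed)

    first_conv = spec.conv_layers()[0]
    filter_indices = config.filter_indices

    fit_rows = []
    modulation_rows = []
    summary: dict = {"config": {**vars(config)}, "taps": {}}
    target = None
    if config.target_path:
        target = pd.read_csv(config.target_path)["mean_modulation"].to_numpy(dtype=float)

    for tap in config.tap_points:
        tap_layers = spec.layers_until(tap)
        last_conv = [l for l in tap_layers if l.kind == "conv"][-1]
        indices = tuple(filter_indices) if filter_indices else tuple(range(last_conv.n_filters))
        selector = feature_model.PopulationSelector(
            filter_indices=indices,
            spatial_neighborhood=config.spatial_neighborhood,
            tap_point=tap,
        )
        tensor = feature_model.compute_response_tensor(ensemble, spec, weights, selector)
        profile = modulation_matrix(tensor)
        valid = np.flatnonzero(profile.valid_mask)
        for f in range(profile.n_families):
            modulation_rows.append(
                {
                    "tap_point": tap,
                    "family": f,
                    "mean_modulation": float(np.nanmean(profile.M_matrix[valid, f]))
                    if valid.size
                    else float("nan"),
                }
            )

        if target is None:
            # planted self-target: the mean profile of a seeded random valid
            # subset of size k, so fits have a realizable reference
            rng = np.random.default_rng(config.seed + 1)
            size = min(config.k, valid.size)
            subset = rng.choice(valid, size=size, replace=False)
            tap_target = synthetic_data.generate_planted_target(profile, subset)
        else:
            tap_target = target

        tap_summary = {"n_valid_neurons": int(valid.size), "target": np.asarray(tap_target).tolist()}
        for method in config.methods:
            k_eff = min(config.k, valid.size)
            fit = _fit(profile, tap_target, method, k_eff, config.lam)
            row = {
                "tap_point": tap,
                "weight_mode": config.weight_mode,
                "method": method,
                "k": k_eff,
                "train_error": fit.train_error,
                "spearman": fit.spearman,
                "r_squared": fit.r_squared,
            }
            if config.cv_scheme == "leave_group_out":
                plan = make_cv_plan(
                    tensor.n_families,
                    tensor.n_samples,
                    config.cv_group_size or tensor.n_samples,
                    seed=config.seed,
                )
                cv = cross_validate(tensor, tap_target, plan, method, k_eff, config.lam)
                row["cv_test_error"] = cv.test_error
                row["cv_mean_test_error"] = cv.mean_test_error
            elif config.cv_scheme == "leave_family_out":
                lfo = leave_family_out(tensor, tap_target, method, k_eff, config.lam)
                row["cv_test_error"] = lfo.test_error
            fit_rows.append(row)
        summary["taps"][tap] = tap_summary

    fits = pd.DataFrame(fit_rows)
    modulation = pd.DataFrame(modulation_rows)
    fits.to_csv(out / "fit_results.csv", index=False)
    modulation.to_csv(out / "modulation_by_family.csv", index=False)
    summary["fit_results"] = fit_rows
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))

    fig, ax = plt.subplots(figsize=(7, 3.5))
    for tap, group in modulation.groupby("tap_point"):
        ax.bar(
            group["family"] + 0.8 * list(config.tap_points).index(tap) / max(len(config.tap_points), 1),
            group["mean_modulation"],
            width=0.8 / max(len(config.tap_points), 1),
            label=tap,
        )
    ax.set_xlabel("texture family")
    ax.set_ylabel("mean modulation index")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "modulation_by_family.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for method, group in fits.groupby("method"):
        ax.plot(group["tap_point"], group["train_error"], marker="o", label=method)
    ax.set_xlabel("tap point")
    ax.set_ylabel("train Euclidean error")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "error_by_layer.png", dpi=120)
    plt.close(fig)

    return summary
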