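"""Population-fitting procedures for matching a target modulation profile.

Given the matrix M whose columns are per-family modulation indices of n
candidate model neurons, and a target vector t of per-family mean indices
from a recorded neural population, three procedures select or weight
model neurons:

* ``greedy_subset`` — forward selection: repeatedly add the neuron that
  minimizes the Euclidean distance between t and the equally weighted
  mean of the selected rows, until k neurons are chosen.  Mirrors the
  analysis of the recordings, where the population index is an unweighted
  average over a fixed number of neurons.
* ``full_population_weights`` — the optimal convex combination: minimize
  ||M'w - t||^2 subject to w >= 0 and sum(w) = 1.  The best any weighted
  average can do; a lower bound on subset errors.
* ``regularized_subset`` — adds a ridge penalty lam*||w||^2 that pushes
  weights toward uniformity, then keeps the k largest-weight neurons and
  re-scores them as an equally weighted average.

Fits are summarized by Euclidean error, Spearman rank correlation, and
explained variance (R^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy import stats

from .texture_sensitivity import ModulationProfile

__all__ = [
    "FitResult",
    "euclidean_error",
    "greedy_subset",
    "full_population_weights",
    "regularized_subset",
    "spearman_correlation",
    "explained_variance",
    "exhaustive_subset",
    "solve_simplex_lsq",
]


def euclidean_error(x, y) -> float:
    """2-norm distance between two equal-length vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.sum((y - x) ** 2)))


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation (Pearson on average-ranked data)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def explained_variance(fitted, target) -> float:
    """R^2 of ``fitted`` against ``target``: 1 - SSE/SST about the target mean."""
    fitted = np.asarray(fitted, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if fitted.shape != target.shape or fitted.ndim != 1:
        raise ValueError("need two equal-length vectors")
    sst = float(np.sum((target - target.mean()) ** 2))
    if sst == 0:
        raise ValueError("explained variance undefined for a zero-variance target")
    sse = float(np.sum((target - fitted) ** 2))
    return 1.0 - sse / sst


@dataclass
class FitResult:
    """Outcome of one fitting procedure.

    ``weights`` lives on the full neuron index range and sums to one;
    subset methods place uniform mass 1/k on ``selected_indices``.
    """

    method: str
    selected_indices: list[int]
    weights: np.ndarray
    fitted: np.ndarray
    train_error: float
    spearman: float
    r_squared: float
    test_error: float | None = None
    lam: float | None = None
    k: int | None = None
    weight_fraction_above_threshold: float | None = None
    extras: dict = field(default_factory=dict)

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        """Weighted population profile under this fit for any index matrix
        with the same neuron axis.  Zero-weight rows are ignored, so NaN
        rows of invalid neurons cannot contaminate the prediction."""
        active = self.weights > 0
        return matrix[active].T @ self.weights[active]

    def to_json(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["weights"] = np.asarray(self.weights).tolist()
        doc["fitted"] = np.asarray(self.fitted).tolist()
        Path(path).write_text(json.dumps(doc, indent=2))


def _validated(profile: ModulationProfile, target) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    target = np.asarray(target, dtype=np.float64)
    if target.ndim != 1 or target.size != profile.n_families:
        raise ValueError(
            f"target length {target.shape} does not match {profile.n_families} families"
        )
    valid = np.flatnonzero(profile.valid_mask)
    if valid.size == 0:
        raise ValueError("insufficient population: no valid neurons to fit")
    return profile.M_matrix[valid], valid, target


def _summarize(fitted: np.ndarray, target: np.ndarray) -> tuple[float, float, float]:
    err = euclidean_error(fitted, target)
    try:
        rho = spearman_correlation(fitted, target)
    except ValueError:
        rho = float("nan")
    try:
        r2 = explained_variance(fitted, target)
    except ValueError:
        r2 = float("nan")
    return err, rho, r2


def greedy_subset(profile: ModulationProfile, target, k: int) -> FitResult:
    """Forward selection of k neurons minimizing the running mean's distance.

    At step j the candidate minimizing || t - mean(selected + candidate) ||
    joins the set; ties break toward the lowest neuron index.  The error of
    the equally weighted k-subset mean is reported as train error.
    """
    rows, valid, target = _validated(profile, target)
    n = rows.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}] valid neurons")

    remaining = np.ones(n, dtype=bool)
    running_sum = np.zeros(profile.n_families)
    chosen: list[int] = []
    for step in range(1, k + 1):
        cand = np.flatnonzero(remaining)
        means = (running_sum[None, :] + rows[cand]) / step
        sq = np.sum((means - target[None, :]) ** 2, axis=1)
        best = cand[int(np.argmin(sq))]  # argmin returns first (lowest index) tie
        chosen.append(int(best))
        remaining[best] = False
        running_sum += rows[best]

    fitted = running_sum / k
    err, rho, r2 = _summarize(fitted, target)
    weights = np.zeros(profile.M_matrix.shape[0])
    weights[valid[chosen]] = 1.0 / k
    return FitResult(
        method="greedy",
        selected_indices=[int(valid[j]) for j in chosen],
        weights=weights,
        fitted=fitted,
        train_error=err,
        spearman=rho,
        r_squared=r2,
        k=k,
    )


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex (sorting method)."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u - css / np.arange(1, v.size + 1) > 0)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def solve_simplex_lsq(
    M: np.ndarray,
    t: np.ndarray,
    lam: float = 0.0,
    tol: float = 1e-9,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Minimize ||Mw - t||^2 + lam*||w||^2 over the probability simplex.

    Accelerated projected gradient (FISTA with restarts).  Convergence is
    declared when the projected-gradient residual ||w - P(w - g/L)||*L
    drops below ``tol``, i.e. the KKT conditions hold to that tolerance.
    M is (families, neurons) here.
    """
    f, n = M.shape
    if n == 1:
        return np.ones(1)
    gram = M.T @ M + lam * np.eye(n)
    lin = M.T @ t
    lipschitz = 2.0 * float(np.linalg.eigvalsh(gram)[-1]) if n <= 1024 else 2.0 * (
        float(np.linalg.norm(gram, 2))
    )
    lipschitz = max(lipschitz, 1e-12)

    w = np.full(n, 1.0 / n)
    z = w.copy()
    t_accel = 1.0
    for it in range(max_iter):
        grad_z = 2.0 * (gram @ z - lin)
        w_new = _project_simplex(z - grad_z / lipschitz)
        # adaptive restart on non-monotone momentum direction
        if np.dot(z - w_new, w_new - w) > 0:
            z, t_accel = w, 1.0
            continue
        t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_accel**2)) / 2.0
        z = w_new + ((t_accel - 1.0) / t_next) * (w_new - w)
        w, t_accel = w_new, t_next
        if it % 10 == 0:
            grad = 2.0 * (gram @ w - lin)
            residual = lipschitz * np.max(np.abs(w - _project_simplex(w - grad / lipschitz)))
            if residual <= tol:
                break
    return w


def full_population_weights(profile: ModulationProfile, target) -> FitResult:
    """Optimal simplex-constrained weighted average over all valid neurons.

    Its train error is the infimum over convex combinations and hence lower
    than (or equal to) any subset method's error on the same inputs.
    """
    rows, valid, target = _validated(profile, target)
    w = solve_simplex_lsq(rows.T, target)
    fitted = rows.T @ w
    err, rho, r2 = _summarize(fitted, target)
    weights = np.zeros(profile.M_matrix.shape[0])
    weights[valid] = w
    return FitResult(
        method="full_population",
        selected_indices=[],
        weights=weights,
        fitted=fitted,
        train_error=err,
        spearman=rho,
        r_squared=r2,
    )


def regularized_subset(
    profile: ModulationProfile,
    target,
    lam: float = 0.8,
    k: int = 103,
    report_threshold: float = 2e-3,
) -> FitResult:
    """Ridge-regularized simplex fit followed by top-k selection.

    The penalty lam*||w||^2 pushes weights toward the simplex center, so
    more neurons carry mass above ``report_threshold`` (the reported
    fraction).  The k largest-weight neurons (ties toward lower index) are
    then re-scored as an equally weighted average — matching how the
    recorded population's modulation index is computed.
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    rows, valid, target = _validated(profile, target)
    n = rows.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}] valid neurons")
    w = solve_simplex_lsq(rows.T, target, lam=lam)
    fraction = float(np.count_nonzero(w >= report_threshold)) / n

    # stable sort on -w keeps lower indices first among ties
    order = np.argsort(-w, kind="stable")
    chosen = np.sort(order[:k])
    fitted = rows[chosen].mean(axis=0)
    err, rho, r2 = _summarize(fitted, target)
    weights = np.zeros(profile.M_matrix.shape[0])
    weights[valid[chosen]] = 1.0 / k
    return FitResult(
        method="regularized",
        selected_indices=[int(valid[j]) for j in chosen],
        weights=weights,
        fitted=fitted,
        train_error=err,
        spearman=rho,
        r_squared=r2,
        lam=lam,
        k=k,
        weight_fraction_above_threshold=fraction,
        extras={"simplex_weights_valid_order": w.tolist()},
    )


def exhaustive_subset(profile: ModulationProfile, target, k: int) -> FitResult:
    """Brute-force minimum over all k-subsets (oracle for small problems)."""
    rows, valid, target = _validated(profile, target)
    n = rows.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    best_err, best_subset, best_fit = np.inf, None, None
    for subset in combinations(range(n), k):
        fitted = rows[list(subset)].mean(axis=0)
        err = euclidean_error(fitted, target)
        if err < best_err:
            best_err, best_subset, best_fit = err, subset, fitted
    err, rho, r2 = _summarize(best_fit, target)
    weights = np.zeros(profile.M_matrix.shape[0])
    weights[valid[list(best_subset)]] = 1.0 / k
    return FitResult(
        method="exhaustive",
        selected_indices=[int(valid[j]) for j in best_subset],
        weights=weights,
        fitted=best_fit,
        train_error=err,
        spearman=rho,
        r_squared=r2,
        k=k,
    )
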