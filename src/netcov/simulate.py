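"""Simulation models, the max-type comparator test, and power/ROC
harnesses.

Two families of generative models are provided:

* **Moving-average models 1-3** for comparing the linear and kernel
  statistics: column k of the output is f(Z_k) + theta * f(Z_{k+1}) with
  i.i.d. standard-normal latents Z and f = identity, cube or exponential.
  theta = 0.5 defines the null; the alternative changes theta in one group
  (to 0.2 or 0.3), altering the covariance structure.  Models 2-3 make the
  dependence between coordinates nonlinear, the regime where the kernel
  statistic should win.

* **Covariance-perturbation models 1-4** for comparing the Frobenius-norm
  test against a max-type (extreme-entry) test: a correlated base
  covariance Sigma = D^{1/2} Sigma* D^{1/2} (Sigma*_ij = 0.5^|i-j|,
  d_ii ~ Unif(0.5, 2.5)) perturbed by a symmetric matrix U with few (8,
  sparse) or many (500, dense) nonzero entries.  Both matrices are shifted
  by delta*I with delta = |min eigenvalue| + 0.05 so they stay positive
  definite.  Sparse alternatives favor the max-type test, dense ones the
  Frobenius-norm test.

The power harness thresholds raw statistics at the empirical null
quantile (no permutations inside the replicate loop); permutation-based
calibration is validated separately in the significance module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covtest import t_statistic
from .kernel import KernelSpec, kernel_matrix
from .covtest import t_from_gram

__all__ = [
    "MAModelSpec",
    "CovModelSpec",
    "PowerCurve",
    "simulate_ma_model",
    "simulate_cov_model",
    "cai_max_statistic",
    "roc_curve",
    "power_ma_models",
    "power_cov_models",
    "power_comparison",
]

THETA_NULL = 0.5  # moving-average coefficient under covariance equality


@dataclass
class MAModelSpec:
    """One moving-average simulation model: X_k = f(Z_k) + theta f(Z_{k+1})."""

    model: int
    p: int
    n: int
    theta: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in (1, 2, 3):
            raise ValueError("model must be 1 (identity), 2 (cube) or 3 (exp)")
        if self.p < 1 or self.n < 4:
            raise ValueError("need p >= 1 and n >= 4")


@dataclass
class CovModelSpec:
    """One covariance-perturbation model.

    ``n_nonzero`` counts total nonzero cells of the symmetric perturbation
    U by default (mirrored pairs count as two); set
    ``count_mirrored_once=True`` for the other reading.
    """

    model: int
    p: int = 50
    n_per_class: int = 50
    seed: int = 0
    count_mirrored_once: bool = False

    _PARAMS = {1: (8, 4.0), 2: (8, 400.0), 3: (500, 4.0), 4: (500, 400.0)}

    def __post_init__(self) -> None:
        if self.model not in self._PARAMS:
            raise ValueError("model must be in 1..4")
        if self.n_nonzero > self.p * self.p:
            raise ValueError("more nonzero entries than matrix cells")

    @property
    def n_nonzero(self) -> int:
        return self._PARAMS[self.model][0]

    @property
    def magnitude_max(self) -> float:
        return self._PARAMS[self.model][1]


@dataclass
class PowerCurve:
    """ROC curve: paired (false-positive rate, true-positive rate) points,
    both non-decreasing, from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray

    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def _ma_transform(Z: np.ndarray, model: int) -> np.ndarray:
    if model == 1:
        return Z
    if model == 2:
        return Z**3
    return np.exp(Z)


def simulate_ma_model(
    spec: MAModelSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw an n x p sample from the moving-average model.

    The latent matrix has p+1 columns so column p of the output uses
    Z_{p+1} without wrap-around.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    Z = rng.standard_normal((spec.n, spec.p + 1))
    F = _ma_transform(Z, spec.model)
    return F[:, : spec.p] + spec.theta * F[:, 1:]


def _symmetric_perturbation(
    p: int, n_nonzero: int, magnitude_max: float, max_sigma: float,
    rng: np.random.Generator, count_mirrored_once: bool,
) -> np.ndarray:
    """Symmetric U with the stated number of nonzero off-diagonal cells at
    random positions, magnitudes Unif(0, magnitude_max) * max_sigma with
    random signs."""
    n_pairs = n_nonzero if count_mirrored_once else n_nonzero // 2
    if not count_mirrored_once and n_nonzero % 2:
        raise ValueError("n_nonzero must be even when mirrored cells count twice")
    iu, ju = np.triu_indices(p, k=1)
    if n_pairs > iu.size:
        raise ValueError("too many nonzero entries for the off-diagonal")
    chosen = rng.choice(iu.size, size=n_pairs, replace=False)
    mags = rng.uniform(0.0, magnitude_max, size=n_pairs) * max_sigma
    signs = rng.choice([-1.0, 1.0], size=n_pairs)
    U = np.zeros((p, p))
    U[iu[chosen], ju[chosen]] = mags * signs
    return U + U.T


def simulate_cov_model(
    spec: CovModelSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build (X1, X2, Sigma1, Sigma2) for one covariance-perturbation
    replicate.

    Sigma1 = Sigma + delta I and Sigma2 = Sigma + U + delta I with
    delta = |min(lambda_min(Sigma + U), lambda_min(Sigma))| + 0.05, so
    Sigma1 - Sigma2 = -U exactly and both matrices are positive definite
    with smallest eigenvalue at least 0.05.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    p = spec.p
    idx = np.arange(p)
    Sigma_star = 0.5 ** np.abs(idx[:, None] - idx[None, :])
    d = rng.uniform(0.5, 2.5, size=p)
    Dh = np.sqrt(d)
    Sigma = Dh[:, None] * Sigma_star * Dh[None, :]
    max_sigma = float(np.max(np.diag(Sigma)))
    U = _symmetric_perturbation(
        p, spec.n_nonzero, spec.magnitude_max, max_sigma, rng, spec.count_mirrored_once
    )
    lam = min(
        np.linalg.eigvalsh(Sigma + U)[0],
        np.linalg.eigvalsh(Sigma)[0],
    )
    delta = abs(lam) + 0.05
    Sigma1 = Sigma + delta * np.eye(p)
    Sigma2 = Sigma + U + delta * np.eye(p)
    L1 = np.linalg.cholesky(Sigma1)
    L2 = np.linalg.cholesky(Sigma2)
    n = spec.n_per_class
    X1 = rng.standard_normal((n, p)) @ L1.T
    X2 = rng.standard_normal((n, p)) @ L2.T
    return X1, X2, Sigma1, Sigma2


def cai_max_statistic(X1: np.ndarray, X2: np.ndarray) -> tuple[float, float]:
    """Max-type covariance equality test: the largest entrywise
    standardized squared difference of sample covariances.

    Each entry (i, j) contributes (s1_ij - s2_ij)^2 / (th1_ij/n1 +
    th2_ij/n2) where th_ij estimates Var((X_i - mu_i)(X_j - mu_j)); the
    p-value comes from the type-I extreme-value limit
    P(M - 4 log p + log log p <= t) -> exp(-exp(-t/2) / sqrt(8 pi)).
    Powerful against sparse alternatives (few large entry differences).
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    n1, p = X1.shape
    n2 = X2.shape[0]
    if n1 < 5 or n2 < 5:
        raise ValueError("max-type test needs at least 5 samples per group")

    def _cov_and_theta(X: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
        Xc = X - X.mean(axis=0)
        S = Xc.T @ Xc / n
        P = Xc[:, :, None] * Xc[:, None, :]  # n x p x p outer products
        theta = ((P - S) ** 2).mean(axis=0)
        return S, theta

    S1, th1 = _cov_and_theta(X1, n1)
    S2, th2 = _cov_and_theta(X2, n2)
    denom = th1 / n1 + th2 / n2
    num = (S1 - S2) ** 2
    degenerate = denom <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} covariance entries with zero variance "
            "excluded from the max-type statistic",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        M = np.where(degenerate, -np.inf, num / denom)
    stat = float(M.max())
    t = stat - 4.0 * np.log(p) + np.log(np.log(p))
    pvalue = float(1.0 - np.exp(-np.exp(-t / 2.0) / np.sqrt(8.0 * np.pi)))
    return stat, min(max(pvalue, 0.0), 1.0)


def roc_curve(null_stats: np.ndarray, alt_stats: np.ndarray) -> PowerCurve:
    """Empirical ROC: sweep the rejection threshold over all observed
    statistic values; FPR from the null sample, TPR from the alternative
    sample; anchored at (0,0) and (1,1)."""
    null_stats = np.asarray(null_stats, dtype=float)
    alt_stats = np.asarray(alt_stats, dtype=float)
    if null_stats.size == 0 or alt_stats.size == 0:
        raise ValueError("need non-empty statistic vectors")
    thresholds = np.unique(np.concatenate([null_stats, alt_stats]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        fpr.append(float(np.mean(null_stats >= t)))
        tpr.append(float(np.mean(alt_stats >= t)))
    fpr.append(1.0)
    tpr.append(1.0)
    fpr_arr = np.array(fpr)
    tpr_arr = np.array(tpr)
    keep = np.ones(fpr_arr.size, dtype=bool)
    keep[1:] = (np.diff(fpr_arr) != 0) | (np.diff(tpr_arr) != 0)
    return PowerCurve(fpr=fpr_arr[keep], tpr=tpr_arr[keep])


def _two_group_stats(
    X1: np.ndarray, X2: np.ndarray, specs: list[KernelSpec]
) -> dict[str, float]:
    """Evaluate several kernel statistics on one dataset, sharing the
    pooled Gram / squared-distance computation across bandwidths."""
    pooled = np.vstack([X1, X2])
    n1 = X1.shape[0]
    idx = [np.arange(n1), np.arange(n1, pooled.shape[0])]
    out: dict[str, float] = {}
    rbf = [s for s in specs if s.family == "rbf"]
    if any(s.family == "linear" for s in specs):
        G = pooled @ pooled.T
        out["linear"] = t_from_gram(G, idx).T
    if rbf:
        from scipy.spatial.distance import squareform, pdist

        D2 = squareform(pdist(pooled, metric="sqeuclidean"))
        for s in rbf:
            K = np.exp(-s.rbf_gamma * D2)
            out[s.label] = t_from_gram(K, idx).T
    return out


DEFAULT_MA_METHODS = [
    KernelSpec("linear"),
    KernelSpec("rbf", bandwidth=1.0),
    KernelSpec("rbf", bandwidth=10.0),
]


def power_ma_models(
    models: list[int],
    p: int = 40,
    n1: int = 60,
    n2: int = 60,
    theta_alt: float = 0.2,
    theta_null: float = THETA_NULL,
    methods: list[KernelSpec] | None = None,
    reps: int = 500,
    alphas: tuple[float, ...] = (0.05,),
    seed: int = 0,
    return_stats: bool = False,
):
    """Power of each statistic on the moving-average models.

    For each replicate, a null dataset (both groups theta = theta_null)
    and an alternative dataset (group 1 theta_null, group 2 theta_alt) are
    generated; the rejection threshold is the empirical (1 - alpha)
    quantile of the null statistics.  Returns a tidy table (model, method,
    size, power) and optionally the raw statistic vectors for ROC curves.
    """
    if reps < 50:
        raise ValueError("need at least 50 replicates")
    methods = methods or DEFAULT_MA_METHODS
    rows = []
    stats_out: dict[tuple[int, str, str], np.ndarray] = {}
    for model in models:
        rng = np.random.default_rng(np.random.SeedSequence([seed, model]))
        null_stats = {m.label: np.empty(reps) for m in methods}
        alt_stats = {m.label: np.empty(reps) for m in methods}
        for r in range(reps):
            s0 = MAModelSpec(model=model, p=p, n=n1, theta=theta_null)
            X1 = simulate_ma_model(s0, rng)
            X2 = simulate_ma_model(MAModelSpec(model=model, p=p, n=n2, theta=theta_null), rng)
            for k, v in _two_group_stats(X1, X2, methods).items():
                null_stats[k][r] = v
            X1a = simulate_ma_model(s0, rng)
            X2a = simulate_ma_model(MAModelSpec(model=model, p=p, n=n2, theta=theta_alt), rng)
            for k, v in _two_group_stats(X1a, X2a, methods).items():
                alt_stats[k][r] = v
        for m in methods:
            for alpha in alphas:
                thr = np.quantile(null_stats[m.label], 1.0 - alpha)
                power = float(np.mean(alt_stats[m.label] >= thr))
                rows.append(
                    {"model": model, "method": m.label, "size": alpha, "power": power}
                )
            stats_out[(model, m.label, "null")] = null_stats[m.label]
            stats_out[(model, m.label, "alt")] = alt_stats[m.label]
    table = pd.DataFrame(rows)
    if return_stats:
        return table, stats_out
    return table


def power_cov_models(
    models: list[int],
    p: int = 50,
    n_per_class: int = 50,
    reps: int = 500,
    alphas: tuple[float, ...] = (0.05,),
    seed: int = 0,
    return_stats: bool = False,
):
    """Power of the Frobenius-norm (``chen``) and max-type (``cai``)
    statistics on the covariance-perturbation models.

    Null replicates draw both groups from Sigma1 of a fresh model
    instance; alternative replicates draw group 2 from Sigma2.
    """
    if reps < 50:
        raise ValueError("need at least 50 replicates")
    rows = []
    stats_out: dict[tuple[int, str, str], np.ndarray] = {}
    for model in models:
        rng = np.random.default_rng(np.random.SeedSequence([seed, model]))
        null_stats = {"chen": np.empty(reps), "cai": np.empty(reps)}
        alt_stats = {"chen": np.empty(reps), "cai": np.empty(reps)}
        spec = CovModelSpec(model=model, p=p, n_per_class=n_per_class)
        for r in range(reps):
            X1, X2, Sigma1, _ = simulate_cov_model(spec, rng)
            L1 = np.linalg.cholesky(Sigma1)
            X2_null = rng.standard_normal((n_per_class, p)) @ L1.T
            null_stats["chen"][r] = t_statistic(X1, X2_null).T
            null_stats["cai"][r] = cai_max_statistic(X1, X2_null)[0]
            alt_stats["chen"][r] = t_statistic(X1, X2).T
            alt_stats["cai"][r] = cai_max_statistic(X1, X2)[0]
        for method in ("chen", "cai"):
            for alpha in alphas:
                thr = np.quantile(null_stats[method], 1.0 - alpha)
                rows.append(
                    {
                        "model": model,
                        "method": method,
                        "size": alpha,
                        "power": float(np.mean(alt_stats[method] >= thr)),
                    }
                )
            stats_out[(model, method, "null")] = null_stats[method]
            stats_out[(model, method, "alt")] = alt_stats[method]
    table = pd.DataFrame(rows)
    if return_stats:
        return table, stats_out
    return table


def power_comparison(
    model_specs: list[MAModelSpec] | list[CovModelSpec],
    methods: list[KernelSpec] | None = None,
    reps: int = 500,
    alphas: tuple[float, ...] = (0.05,),
    seed: int = 0,
) -> pd.DataFrame:
    """Dispatch a power study from model specs (moving-average specs run
    the linear/kernel comparison; covariance specs run Frobenius vs
    max-type)."""
    if not model_specs:
        raise ValueError("no models given")
    first = model_specs[0]
    if isinstance(first, MAModelSpec):
        return power_ma_models(
            [s.model for s in model_specs],
            p=first.p,
            n1=first.n,
            n2=first.n,
            theta_alt=first.theta,
            methods=methods,
            reps=reps,
            alphas=alphas,
            seed=seed,
        )
    return power_cov_models(
        [s.model for s in model_specs],
        p=first.p,
        n_per_class=first.n_per_class,
        reps=reps,
        alphas=alphas,
        seed=seed,
    )
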