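"""Permutation significance, size-normalized statistics and tail-ratio FDR.

Three-step machinery for module selection:

1. a genotype-label permutation null for each module (label shuffling keeps
   the gene-gene correlation structure intact, so the null reflects "no
   genotype effect on covariance" rather than "no correlation at all");
2. a size normalization NT = T / mean(same-sign null values), making
   statistics comparable across gene sets of different sizes;
3. an FDR estimated by comparing the tails of the observed and pooled
   null NT distributions, with Storey-style monotonization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PermutationNull",
    "NormalizedResult",
    "permutation_null",
    "permutation_null_gram",
    "nominal_p",
    "normalize_statistic",
    "fdr_qvalues",
]


@dataclass
class PermutationNull:
    """B statistics recomputed under random permutations of the genotype
    labels (group sizes preserved exactly)."""

    values: np.ndarray
    B: int
    seed: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.B,):
            raise ValueError("null length must equal B")
        if self.B < 1:
            raise ValueError("need at least one permutation")


@dataclass
class NormalizedResult:
    NT_observed: float
    NT_null: np.ndarray


def _groups_from_labels(labels: np.ndarray) -> list[np.ndarray]:
    classes = np.unique(labels)
    return [np.flatnonzero(labels == c) for c in classes]


def permutation_null(
    pooled: np.ndarray,
    labels: Sequence[int],
    stat_fn: Callable[[list[np.ndarray]], float],
    B: int,
    seed: int,
) -> PermutationNull:
    """Evaluate ``stat_fn`` on B label-permuted splits of the pooled sample
    matrix (rows = samples).

    ``stat_fn`` receives the list of group matrices in ascending label
    order.  Permutation b applies ``rng.permutation(n)`` to the label
    vector, so group sizes are preserved exactly; the stream is fully
    determined by ``seed``.
    """
    pooled = np.asarray(pooled, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != pooled.shape[0]:
        raise ValueError("labels and pooled rows must align")
    n_classes = np.unique(labels).size
    if n_classes not in (2, 3):
        raise ValueError("labels must define 2 or 3 groups")
    rng = np.random.default_rng(seed)
    out = np.empty(B, dtype=float)
    for b in range(B):
        perm = rng.permutation(labels.shape[0])
        permuted = labels[perm]
        groups = _groups_from_labels(permuted)
        try:
            out[b] = stat_fn([pooled[g] for g in groups])
        except Exception as exc:  # pragma: no cover - context for debugging
            raise RuntimeError(f"statistic failed on permutation {b}: {exc}") from exc
    return PermutationNull(values=out, B=B, seed=seed)


def permutation_null_gram(
    K: np.ndarray,
    labels: np.ndarray,
    B: int,
    seed: int,
    stat_from_gram: Callable[[np.ndarray, list[np.ndarray]], float],
) -> PermutationNull:
    """Permutation null evaluated from a precomputed pooled Gram/kernel
    matrix.

    Labels are permuted, not data: each permutation only reindexes rows and
    columns of ``K``, so the kernel is evaluated once per module rather
    than once per permutation.  Uses the same permutation stream as
    :func:`permutation_null`.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    out = np.empty(B, dtype=float)
    for b in range(B):
        perm = rng.permutation(labels.shape[0])
        groups = _groups_from_labels(labels[perm])
        out[b] = stat_from_gram(K, groups)
    return PermutationNull(values=out, B=B, seed=seed)


def nominal_p(observed: float, null: PermutationNull) -> float:
    """One-sided permutation p-value with the plus-one rule:
    p = (1 + #{null >= observed}) / (B + 1); large T indicates departure
    from covariance equality."""
    return (1.0 + float(np.sum(null.values >= observed))) / (null.B + 1.0)


def normalize_statistic(observed: float, null: PermutationNull) -> NormalizedResult:
    """Size-normalize a statistic against its own permutation null.

    Sign-preserving normalization: non-negative values are divided by the
    mean of the non-negative null values, negative values by the mean
    magnitude of the negative null values (so NT keeps the sign of T and
    is invariant to rescaling all statistics by a positive constant).  If
    the null contains no value of the needed sign the result is NaN, with
    a warning; such modules are excluded from FDR.
    """
    vals = null.values

    def _norm(v: float) -> float:
        if v >= 0:
            pos = vals[vals >= 0]
            if pos.size == 0 or pos.mean() == 0.0:
                return np.nan
            return v / pos.mean()
        neg = vals[vals < 0]
        if neg.size == 0:
            return np.nan
        return v / np.abs(neg).mean()

    nt_obs = _norm(observed)
    if np.isnan(nt_obs):
        warnings.warn(
            "no null values with the sign of the observed statistic; "
            "NT undefined for this module",
            stacklevel=2,
        )
    nt_null = np.array([_norm(v) for v in vals])
    return NormalizedResult(NT_observed=nt_obs, NT_null=nt_null)


def fdr_qvalues(observed_NT: Sequence[float], null_NT: Sequence[float]) -> np.ndarray:
    """Tail-ratio FDR q-values.

    For each observed NT value v the raw estimate is

        q_raw(v) = (fraction of pooled null NT >= v)
                   / (fraction of observed NT >= v)

    clipped to [0, 1]; the q-value is then the minimum of q_raw over all
    thresholds t <= v (every more liberal rejection set containing the
    module), which enforces monotone non-increasing q in NT.
    """
    obs = np.asarray(observed_NT, dtype=float)
    null = np.asarray(null_NT, dtype=float)
    if obs.size == 0 or null.size == 0:
        raise ValueError("observed and null NT vectors must be non-empty")
    null = null[~np.isnan(null)]
    finite = ~np.isnan(obs)
    q = np.full(obs.shape, np.nan)
    if not finite.any() or null.size == 0:
        return q
    v = obs[finite]
    null_sorted = np.sort(null)
    obs_sorted = np.sort(v)
    frac_null = 1.0 - np.searchsorted(null_sorted, v, side="left") / null.size
    frac_obs = 1.0 - np.searchsorted(obs_sorted, v, side="left") / v.size
    raw = np.clip(frac_null / frac_obs, 0.0, 1.0)
    # monotonize: ascending in v, q(v) = min of raw over thresholds <= v
    order = np.argsort(v, kind="mergesort")
    mono = np.empty_like(raw)
    running = np.inf
    for i in order:
        running = min(running, raw[i])
        mono[i] = running
    q[finite] = mono
    return q
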