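"""Unbiased U-statistic test for equality of high-dimensional covariance
matrices between genotype groups.

The statistic targets tr((Sigma_1 - Sigma_2)^2), the squared Frobenius norm
of the covariance difference:

    T = A_1 + A_2 - 2*C_12

where A_h is an unbiased estimator of tr(Sigma_h^2) built from sums over
pairwise-distinct sample index tuples within group h, and C_12 is an
unbiased estimator of tr(Sigma_1 Sigma_2) built from cross-group sums.
Because the distinct-index sums remove the terms a plug-in estimator would
contaminate with E||X||^4 moments, the test remains valid when the number
of genes p exceeds the group sizes.  Data are assumed mean-centered
upstream (the adjustment module's contract); the statistic does not
re-center internally.

The fast path evaluates every distinct-index sum from Gram matrices
(entries x_i' x_j) by inclusion-exclusion over coincident indices, at
O(n^2) cost instead of the literal O(n^4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CovTestStatistic",
    "a_term",
    "c_term",
    "t_statistic",
    "t_statistic_three",
]

MIN_GROUP = 4  # n(n-1)(n-2)(n-3) denominators require at least 4 samples


@dataclass
class CovTestStatistic:
    """A covariance-difference statistic with its A/C components.

    For two groups ``T = A[0] + A[1] - 2*C[(0, 1)]`` exactly; for three
    groups ``T = T_12 + T_23`` where each pairwise term has the same form.
    """

    T: float
    method: str
    n_groups: int
    A: list[float] = field(default_factory=list)
    C: dict[tuple[int, int], float] = field(default_factory=dict)


def _as_group(X: np.ndarray, min_rows: int = MIN_GROUP) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("group matrix must be 2-dimensional (samples x genes)")
    if X.shape[0] < min_rows:
        raise ValueError(
            f"group too small for unbiased estimator (n={X.shape[0]} < {min_rows})"
        )
    if X.shape[1] < 1:
        raise ValueError("group matrix needs at least one gene")
    if not np.all(np.isfinite(X)):
        raise ValueError("group matrix contains non-finite values")
    return X


def a_from_gram(G: np.ndarray) -> float:
    """A_n from the within-group Gram matrix G (g_ij = x_i' x_j or a kernel
    evaluation k(x_i, x_j); the diagonal must be present).

    The three distinct-index sums are recovered by inclusion-exclusion:

    * pairs i != j:                 sum g_ij^2 over the off-diagonal;
    * triples (i, j, k) distinct:   sum g_ij g_jk = all-index total minus
      the i=j, j=k and i=k slices plus twice the fully-coincident slice;
    * quadruples distinct:          with B = G minus its diagonal,
      sum g_ij g_kl = (sum B)^2 - 4 sum_i (row_i B)^2 + 2 sum B^2.
    """
    G = np.asarray(G, dtype=float)
    n = G.shape[0]
    if n < MIN_GROUP:
        raise ValueError(f"group too small for unbiased estimator (n={n} < {MIN_GROUP})")
    d = np.diag(G).copy()
    B = G - np.diag(d)
    tot2 = float(np.sum(G * G))
    tot2B = float(np.sum(B * B))
    r = G.sum(axis=1)

    s1 = tot2B
    s2 = float(np.sum(r * r)) - 2.0 * float(np.sum(d * r)) - tot2 + 2.0 * float(np.sum(d * d))
    rB = B.sum(axis=1)
    s3 = float(B.sum()) ** 2 - 4.0 * float(np.sum(rB * rB)) + 2.0 * tot2B

    return (
        s1 / (n * (n - 1))
        - 2.0 * s2 / (n * (n - 1) * (n - 2))
        + s3 / (n * (n - 1) * (n - 2) * (n - 3))
    )


def c_from_gram(H: np.ndarray) -> float:
    """C_{n1 n2} from the cross-group Gram matrix H (h_ij = x_1i' x_2j or
    k(x_1i, x_2j))."""
    H = np.asarray(H, dtype=float)
    n1, n2 = H.shape
    if n1 < 2 or n2 < 2:
        raise ValueError("c_term needs at least 2 samples per group")
    tot2 = float(np.sum(H * H))
    row = H.sum(axis=1)  # over group-2 index, one value per group-1 sample
    col = H.sum(axis=0)
    sr = float(np.sum(row * row))
    sc = float(np.sum(col * col))
    S = float(H.sum())
    return (
        tot2 / (n1 * n2)
        - (sc - tot2) / (n1 * n2 * (n1 - 1))
        - (sr - tot2) / (n1 * n2 * (n2 - 1))
        + (S * S - sr - sc + tot2) / (n1 * n2 * (n1 - 1) * (n2 - 1))
    )


def t_from_gram(K: np.ndarray, groups: list[np.ndarray], method: str = "linear") -> CovTestStatistic:
    """Assemble the two- or three-group statistic from a pooled Gram (or
    kernel) matrix and per-group row indices.

    This is the hot path for permutation tests: the pooled matrix is built
    once and only the index sets change across permutations.
    """
    if len(groups) not in (2, 3):
        raise ValueError("test defined for 2 or 3 genotype groups")
    A = [a_from_gram(K[np.ix_(g, g)]) for g in groups]
    C: dict[tuple[int, int], float] = {}
    for i, j in zip(range(len(groups) - 1), range(1, len(groups))):
        C[(i, j)] = c_from_gram(K[np.ix_(groups[i], groups[j])])
    if len(groups) == 2:
        T = A[0] + A[1] - 2.0 * C[(0, 1)]
    else:
        T = (A[0] + A[1] - 2.0 * C[(0, 1)]) + (A[1] + A[2] - 2.0 * C[(1, 2)])
    return CovTestStatistic(T=T, method=method, n_groups=len(groups), A=A, C=C)


def a_term(X: np.ndarray) -> float:
    """Unbiased estimator A_n of tr(Sigma^2) from one group's samples
    (rows)."""
    X = _as_group(X)
    return a_from_gram(X @ X.T)


def c_term(X1: np.ndarray, X2: np.ndarray) -> float:
    """Unbiased estimator C_{n1 n2} of tr(Sigma_1 Sigma_2); symmetric in
    its arguments."""
    X1 = _as_group(X1, min_rows=2)
    X2 = _as_group(X2, min_rows=2)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"gene dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}"
        )
    return c_from_gram(X1 @ X2.T)


def t_statistic(X1: np.ndarray, X2: np.ndarray) -> CovTestStatistic:
    """Two-group covariance equality statistic T = A_1 + A_2 - 2 C_12."""
    X1 = _as_group(X1)
    X2 = _as_group(X2)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"gene dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}"
        )
    pooled = np.vstack([X1, X2])
    K = pooled @ pooled.T
    n1 = X1.shape[0]
    idx = [np.arange(n1), np.arange(n1, n1 + X2.shape[0])]
    return t_from_gram(K, idx, method="linear")


def t_statistic_three(X1: np.ndarray, X2: np.ndarray, X3: np.ndarray) -> CovTestStatistic:
    """Three-group statistic T_12 + T_23 for H0: Sigma_1 = Sigma_2 = Sigma_3.

    Uses the ordered pairing (1,2) and (2,3) — groups ordered by ascending
    genotype code — so an alternative confined to Sigma_1 != Sigma_3 alone
    is not targeted.
    """
    mats = [_as_group(X) for X in (X1, X2, X3)]
    p = {m.shape[1] for m in mats}
    if len(p) != 1:
        raise ValueError("gene dimension mismatch between groups")
    pooled = np.vstack(mats)
    K = pooled @ pooled.T
    sizes = [m.shape[0] for m in mats]
    offs = np.concatenate([[0], np.cumsum(sizes)])
    idx = [np.arange(offs[i], offs[i + 1]) for i in range(3)]
    return t_from_gram(K, idx, method="linear")
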