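"""Independent brute-force oracles: literal nested-loop evaluation of the
distinct-index U-statistic sums, for checking the Gram-matrix fast path.

These deliberately share no code with the package internals beyond the
kernel evaluations themselves.
"""

import itertools

import numpy as np


def gram_linear(X, Y=None):
    Y = X if Y is None else Y
    return np.asarray(X) @ np.asarray(Y).T


def gram_rbf(X, Y=None, sigma=1.0):
    X = np.asarray(X)
    Y = X if Y is None else np.asarray(Y)
    d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * sigma**2))


def brute_a_from_gram(G):
    n = G.shape[0]
    s1 = sum(G[i, j] ** 2 for i, j in itertools.permutations(range(n), 2))
    s2 = sum(G[i, j] * G[j, k] for i, j, k in itertools.permutations(range(n), 3))
    s3 = sum(
        G[i, j] * G[k, l] for i, j, k, l in itertools.permutations(range(n), 4)
    )
    return (
        s1 / (n * (n - 1))
        - 2.0 * s2 / (n * (n - 1) * (n - 2))
        + s3 / (n * (n - 1) * (n - 2) * (n - 3))
    )


def brute_c_from_gram(H):
    n1, n2 = H.shape
    t1 = sum(H[i, j] ** 2 for i in range(n1) for j in range(n2))
    t2 = sum(
        H[i, j] * H[k, j]
        for i, k in itertools.permutations(range(n1), 2)
        for j in range(n2)
    )
    t3 = sum(
        H[j, i] * H[j, k]
        for i, k in itertools.permutations(range(n2), 2)
        for j in range(n1)
    )
    t4 = sum(
        H[i, j] * H[k, l]
        for i, k in itertools.permutations(range(n1), 2)
        for j, l in itertools.permutations(range(n2), 2)
    )
    return (
        t1 / (n1 * n2)
        - t2 / (n1 * n2 * (n1 - 1))
        - t3 / (n1 * n2 * (n2 - 1))
        + t4 / (n1 * n2 * (n1 - 1) * (n2 - 1))
    )


def brute_t(X1, X2, kernel=gram_linear):
    return (
        brute_a_from_gram(kernel(X1))
        + brute_a_from_gram(kernel(X2))
        - 2.0 * brute_c_from_gram(kernel(X1, X2))
    )


def brute_t_three(X1, X2, X3, kernel=gram_linear):
    return brute_t(X1, X2, kernel) + brute_t(X2, X3, kernel)
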