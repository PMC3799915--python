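"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the CSP reference goes
through explicit whitening instead of the generalized eigensolver, and the
Rayleigh-quotient search uses only random unit directions.
"""

import numpy as np


def reference_regularized_csp(epochs, epsilon, m):
    """Regularized CSP on the raw channels via the classic whitening route.

    Whiten the regularized composite covariance, eigendecompose the
    whitened class-1 covariance, map the eigenvectors back, then apply the
    same unit-norm/sign convention and pair selection as the package.
    Returns ``(W, eigvals, log-variance features)``.
    """
    C = epochs.n_channels
    l1, l2 = np.unique(epochs.labels)
    S = {}
    for cond, lab in ((1, l1), (2, l2)):
        mats = [
            (X @ X.T) / np.trace(X @ X.T)
            for X in epochs.data[epochs.labels == lab]
        ]
        M = np.mean(mats, axis=0)
        S[cond] = M / np.trace(M)
    A = S[1] + epsilon * np.eye(C)
    B = S[1] + S[2] + 2 * epsilon * np.eye(C)
    d, U = np.linalg.eigh(B)
    wh = U @ np.diag(d ** -0.5) @ U.T
    lam, V = np.linalg.eigh(wh @ A @ wh)
    lam, V = lam[::-1], V[:, ::-1]
    F = wh @ V
    F /= np.linalg.norm(F, axis=0)
    piv = np.abs(F).argmax(axis=0)
    F *= np.sign(F[piv, np.arange(C)])
    cols = list(range(m)) + [C - 1 - j for j in range(m)]
    W = F[:, cols]
    feats = np.array(
        [[np.log(np.var(w @ X, ddof=1)) for w in W.T] for X in epochs.data]
    )
    return W, lam[cols], feats


def rayleigh_random_search(A, B, rng, n_total=100_000, n_rounds=20):
    """Extremize w'Aw / w'Bw over random unit directions.

    Adaptive random search: a uniform first round, then Gaussian
    perturbations of the incumbent with geometrically shrinking scale.
    Total budget ``n_total`` directions; never touches an eigensolver.
    Returns ``(max, min)`` of the quotient.
    """
    D = A.shape[0]
    per = n_total // (2 * n_rounds)
    out = {}
    for sign in (1.0, -1.0):
        center, scale, val = None, 1.0, -np.inf
        for _ in range(n_rounds):
            U = rng.standard_normal((per, D))
            if center is not None:
                U = center[None, :] + scale * U
            U /= np.linalg.norm(U, axis=1, keepdims=True)
            q = sign * np.einsum("nd,de,ne->n", U, A, U) / np.einsum(
                "nd,de,ne->n", U, B, U
            )
            i = q.argmax()
            if q[i] > val:
                val, center = q[i], U[i]
            scale *= 0.45
        out[sign] = sign * val
    return out[1.0], out[-1.0]


def random_spd_pair(rng, D):
    """Two trace-normalized Wishart-style SPD matrices of size D."""
    def one():
        M = rng.standard_normal((D, 2 * D))
        S = M @ M.T
        return S / np.trace(S)

    return one(), one()
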