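"""Independent reference implementations used only by the tests.

Each oracle is written from the defining formula with no shared code
paths: the semivariogram by explicit pair enumeration, ordinary kriging
through the variogram-form (not covariance-form) system, and the
pure-nugget leave-one-out predictor as an arithmetic mean.
"""
import numpy as np


def brute_force_variogram(x, y, z, lag_width, max_lag):
    """Eq.-style estimator by explicit enumeration of unordered pairs.

    Returns (bin_index -> (n_pairs, gamma, mean_distance)) for non-empty
    bins below max_lag.
    """
    n = len(x)
    bins = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(x[i] - x[j], y[i] - y[j]))
            if d >= max_lag:
                continue
            k = int(d // lag_width)
            cnt, ssq, dsum = bins.get(k, (0, 0.0, 0.0))
            bins[k] = (cnt + 1, ssq + (z[i] - z[j]) ** 2, dsum + d)
    return {k: (cnt, ssq / (2.0 * cnt), dsum / cnt)
            for k, (cnt, ssq, dsum) in bins.items()}


def variogram_form_ok_weights(coords, target, gamma_fn):
    """Ordinary-kriging weights from the variogram-form system.

    Solves [Gamma, 1; 1^T, 0] [lambda; -mu] = [gamma0; 1] with
    Gamma_ij = gamma(|x_i - x_j|); algebraically equivalent to the
    covariance-form system but assembled entirely differently.
    """
    n = coords.shape[0]
    lhs = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            if i != j:
                lhs[i, j] = gamma_fn(float(np.linalg.norm(coords[i]
                                                          - coords[j])))
        lhs[i, n] = 1.0
        lhs[n, i] = 1.0
    rhs = np.empty(n + 1)
    for i in range(n):
        rhs[i] = gamma_fn(float(np.linalg.norm(coords[i] - target)))
    rhs[n] = 1.0
    return np.linalg.solve(lhs, rhs)[:n]


def loo_means(values):
    """Leave-one-out arithmetic means: prediction of a pure-nugget model."""
    values = np.asarray(values, dtype=float)
    total = values.sum()
    return (total - values) / (values.size - 1)
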