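"""Independent brute-force oracles shared across test modules."""

import numpy as np
from scipy.signal import fftconvolve


def dense_conv_oracle(f, t_s, rate_per_min):
    """Trapezoid-corrected FFT convolution with e^(-rate t) on a dense grid.

    Integration in minutes; error O(dt^2) in the grid step.
    """
    t_min = np.asarray(t_s, dtype=float) / 60.0
    dt = t_min[1] - t_min[0]
    kernel = np.exp(-rate_per_min * t_min)
    conv = fftconvolve(f, kernel)[: len(f)] * dt
    conv -= 0.5 * dt * (f[0] * kernel + f * kernel[0])
    return conv


def brute_force_nnls(a, y):
    """Active-set enumeration oracle: best non-negative LS over all support sets."""
    import itertools

    best_w, best_r = np.zeros(a.shape[1]), float(np.dot(y, y))
    for k in range(1, a.shape[1] + 1):
        for support in itertools.combinations(range(a.shape[1]), k):
            sub = a[:, support]
            w, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.any(w < 0):
                continue
            r = float(((y - sub @ w) ** 2).sum())
            if r < best_r - 1e-12:
                best_r = r
                best_w = np.zeros(a.shape[1])
                best_w[list(support)] = w
    return best_w


def moment_matched_sample(mean, sd, n, rng):
    """A dataset with exactly the requested mean and (ddof=1) SD."""
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x
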