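"""Independent reference implementations used only as test oracles.

These deliberately re-derive results by the most transparent route available
(coordinate descent written from the subgradient equations, Newton iteration
on the logistic likelihood, closed-form rank statistics, brute-force pixel
scans) and share no code with the package paths they check.
"""

from __future__ import annotations

import numpy as np


def lasso_coordinate_descent(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    n_iter: int = 20000,
    tol: float = 1e-12,
) -> tuple[float, np.ndarray]:
    """Minimize (1/2m)||y - b0 - X b||^2 + lam * ||b||_1 by cyclic coordinate
    descent with exact soft-thresholding updates.  Returns (intercept, coef)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    m, p = X.shape
    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    beta = np.zeros(p)
    col_sq = (xc**2).sum(axis=0) / m
    resid = yc - xc @ beta
    for _ in range(n_iter):
        max_delta = 0.0
        for j in range(p):
            if col_sq[j] == 0:
                continue
            rho = (xc[:, j] @ resid) / m + col_sq[j] * beta[j]
            new = np.sign(rho) * max(abs(rho) - lam, 0.0) / col_sq[j]
            delta = new - beta[j]
            if delta != 0.0:
                resid -= xc[:, j] * delta
                beta[j] = new
                max_delta = max(max_delta, abs(delta))
        if max_delta < tol:
            break
    intercept = y.mean() - X.mean(axis=0) @ beta
    return float(intercept), beta


def logistic_newton(x: np.ndarray, y01: np.ndarray, n_iter: int = 100) -> float:
    """Slope of a simple logistic regression (intercept + slope) by Newton's
    method on the exact likelihood; returns the slope coefficient."""
    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, float)])
    y = np.asarray(y01, dtype=float)
    beta = np.zeros(2)
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * W[:, None])
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < 1e-12:
            break
    return float(beta[1])


def spearman_no_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Closed form 1 - 6*sum(d^2)/(n(n^2-1)); valid only without ties."""
    x = np.asarray(x)
    y = np.asarray(y)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = np.sum((rx - ry) ** 2)
    n = len(x)
    return float(1 - 6 * d2 / (n * (n**2 - 1)))


def window_label_fraction(mask: np.ndarray, r: int, c: int, side: int, label: int) -> float:
    """Brute-force pixel scan of one window's label fraction."""
    count = 0
    for i in range(r, r + side):
        for j in range(c, c + side):
            if mask[i, j] == label:
                count += 1
    return count / (side * side)


def gaussian_kernel_1d(sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def bandpass_energy_direct(channel: np.ndarray, sigma_lo: float, sigma_hi: float) -> float:
    """Difference-of-Gaussians band energy via explicit separable convolution
    (scipy.signal, half-sample-symmetric padding) — independent of the
    ndimage filter path."""
    from scipy.signal import convolve2d

    def blur(img, sigma):
        k = gaussian_kernel_1d(sigma)
        r = len(k) // 2
        padded = np.pad(img, r, mode="symmetric")
        out = convolve2d(padded, k[None, :], mode="same")
        out = convolve2d(out, k[:, None], mode="same")
        return out[r:-r, r:-r]

    band = blur(channel, sigma_lo) - blur(channel, sigma_hi)
    return float(band.std())


def expected_binary_kappa(
    agreement: float,
    p0: float,
    p1: float,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo expectation of Cohen's kappa for one binary parameter
    under the copy-or-redraw rater process, simulated directly from its
    description: truth ~ Bernoulli(p0 + (p1-p0)*severity) with severity
    ~ U(0,1); each rater copies the truth with probability ``agreement``,
    else draws from the severity-marginalized Bernoulli."""
    rng = np.random.default_rng(seed)
    sev = rng.uniform(size=n_mc)
    p = p0 + (p1 - p0) * sev
    truth = rng.uniform(size=n_mc) < p
    p_marg = (p0 + p1) / 2
    raters = []
    for _ in range(2):
        copy = rng.uniform(size=n_mc) < agreement
        redraw = rng.uniform(size=n_mc) < p_marg
        raters.append(np.where(copy, truth, redraw))
    a, b = raters
    p_o = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    p_e = pa * pb + (1 - pa) * (1 - pb)
    return float((p_o - p_e) / (1 - p_e))


def simulate_proportional_odds(
    n: int,
    beta: float,
    cutpoints: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinal outcomes from the proportional-odds data-generating process:
    latent = beta*x + logistic noise, categorized at the cutpoints."""
    x = rng.normal(size=n)
    latent = beta * x + rng.logistic(size=n)
    y = np.digitize(latent, cutpoints)
    return y, x
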