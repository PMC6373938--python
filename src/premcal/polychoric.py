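"""Polychoric correlation for ordinal response data.

Two-step maximum likelihood: thresholds are fixed at the normal quantiles of
the observed marginal category proportions, then the latent correlation is
estimated by maximising the bivariate-normal likelihood of the contingency
table.  Rectangle probabilities use a vectorised bivariate normal CDF built
from Owen's T function, which keeps full-matrix estimation fast enough for
banks of 60+ items.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize, stats
from scipy.special import owens_t

__all__ = ["bvn_cdf", "polychoric_corr", "polychoric_matrix", "nearest_positive_definite"]

_EPS = 1e-12


def bvn_cdf(h, k, rho: float) -> np.ndarray:
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)`` (Owen, 1956).

    ``h`` and ``k`` broadcast; infinite bounds are handled exactly.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    h, k = np.broadcast_arrays(h, k)
    rho = float(np.clip(rho, -1.0, 1.0))
    if rho == 0.0:
        return stats.norm.cdf(h) * stats.norm.cdf(k)
    if rho == 1.0:
        return stats.norm.cdf(np.minimum(h, k))
    if rho == -1.0:
        return np.clip(stats.norm.cdf(h) + stats.norm.cdf(k) - 1.0, 0.0, 1.0)

    out = np.empty(h.shape)
    hin = np.isinf(h)
    kin = np.isinf(k)
    # infinite edges reduce to univariate or trivial cases
    out[hin & (h < 0)] = 0.0
    out[kin & (k < 0)] = 0.0
    pos_h = hin & (h > 0)
    pos_k = kin & (k > 0)
    out[pos_h] = stats.norm.cdf(k[pos_h])
    out[pos_k & ~hin] = stats.norm.cdf(h[pos_k & ~hin])
    out[pos_h & pos_k] = 1.0

    fin = ~hin & ~kin
    if fin.any():
        # nudge exact zeros so the T-function arguments stay finite; the CDF
        # is continuous so the perturbation is harmless
        hf = np.where(np.abs(h[fin]) < _EPS, _EPS, h[fin])
        kf = np.where(np.abs(k[fin]) < _EPS, _EPS, k[fin])
        denom = np.sqrt(1.0 - rho * rho)
        a1 = (kf - rho * hf) / (hf * denom)
        a2 = (hf - rho * kf) / (kf * denom)
        val = 0.5 * (stats.norm.cdf(hf) + stats.norm.cdf(kf)) - owens_t(hf, a1) - owens_t(kf, a2)
        prod = hf * kf
        beta = np.where((prod > 0) | ((prod == 0) & (hf + kf >= 0)), 0.0, 0.5)
        out[fin] = np.clip(val - beta, 0.0, 1.0)
    return out


def _thresholds(codes: np.ndarray, n_cat: int) -> np.ndarray:
    """Normal quantiles of the cumulative marginal proportions (len n_cat+1
    including the infinite edges)."""
    counts = np.bincount(codes, minlength=n_cat).astype(float)
    cum = np.cumsum(counts) / counts.sum()
    inner = stats.norm.ppf(np.clip(cum[:-1], 1e-10, 1 - 1e-10))
    return np.concatenate([[-np.inf], inner, [np.inf]])


def polychoric_corr(x, y) -> float:
    """Two-step ML polychoric correlation of two integer-coded ordinal vectors.

    Pairs with a missing value (NaN) are dropped.  Degenerate inputs (a
    variable with a single observed category) return NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    both = ~np.isnan(x) & ~np.isnan(y)
    xi = x[both].astype(int)
    yi = y[both].astype(int)
    if xi.size < 5:
        return np.nan
    # drop empty categories so thresholds are strictly increasing
    xi = np.unique(xi, return_inverse=True)[1]
    yi = np.unique(yi, return_inverse=True)[1]
    kx, ky = xi.max() + 1, yi.max() + 1
    if kx < 2 or ky < 2:
        return np.nan
    table = np.zeros((kx, ky))
    np.add.at(table, (xi, yi), 1.0)
    tx = _thresholds(xi, kx)
    ty = _thresholds(yi, ky)
    hh, kk = np.meshgrid(tx, ty, indexing="ij")

    def neg_loglik(rho: float) -> float:
        c = bvn_cdf(hh, kk, rho)
        cell = c[1:, 1:] - c[:-1, 1:] - c[1:, :-1] + c[:-1, :-1]
        return -float(np.sum(table * np.log(np.clip(cell, 1e-12, None))))

    res = optimize.minimize_scalar(neg_loglik, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def polychoric_matrix(responses: np.ndarray, min_pairs: int = 10) -> np.ndarray:
    """Pairwise-complete polychoric correlation matrix.

    ``responses``: float array (n_persons, n_items) with NaN for missing.
    Uncomputable pairs fall back to 0 with a warning; the result is smoothed
    to the nearest positive semi-definite matrix if needed.
    """
    n_items = responses.shape[1]
    r = np.eye(n_items)
    fallback = 0
    for j in range(n_items):
        for l in range(j + 1, n_items):
            both = ~np.isnan(responses[:, j]) & ~np.isnan(responses[:, l])
            if both.sum() < min_pairs:
                val = np.nan
            else:
                val = polychoric_corr(responses[:, j], responses[:, l])
            if not np.isfinite(val):
                val = 0.0
                fallback += 1
            r[j, l] = r[l, j] = val
    if fallback:
        warnings.warn(f"{fallback} item pair(s) had no estimable polychoric correlation; set to 0")
    eigvals = np.linalg.eigvalsh(r)
    if eigvals.min() < -1e-8:
        warnings.warn("polychoric matrix not positive semi-definite; smoothing to nearest PD")
        r = nearest_positive_definite(r)
    return r


def nearest_positive_definite(r: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped PSD approximation with unit diagonal restored."""
    vals, vecs = np.linalg.eigh(r)
    vals = np.clip(vals, floor, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out
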