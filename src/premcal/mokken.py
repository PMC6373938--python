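"""Non-parametric (Mokken-style) screening of a polytomous scale.

Three checks run before any parametric calibration:

* Loevinger scalability coefficients ``H_ij = cov(X_i, X_j) / cov_max``,
  where ``cov_max`` is the covariance attained by the maximally concordant
  (comonotonic) joint distribution with the same marginals; item- and
  scale-level coefficients aggregate the pairwise numerators and denominators.
* Monotonicity of the item step response functions ``P(X >= k | rest score)``
  across rest-score groups.
* Horn-style parallel analysis of the (polychoric) correlation matrix to
  check unidimensionality against Monte-Carlo reference eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import ResponseMatrix
from .polychoric import polychoric_matrix

__all__ = [
    "MokkenResult",
    "ParallelAnalysisResult",
    "loevinger_coefficients",
    "check_monotonicity",
    "parallel_analysis",
    "mokken_screen",
]


@dataclass
class MokkenResult:
    item_H: dict[str, float] = field(default_factory=dict)
    pair_H: dict[tuple[str, str], float] = field(default_factory=dict)
    scale_H: float = np.nan
    monotonicity: dict[str, dict] = field(default_factory=dict)
    flagged_scalability: list[str] = field(default_factory=list)
    flagged_monotonicity: list[str] = field(default_factory=list)

    @property
    def flagged_items(self) -> list[str]:
        out = list(self.flagged_scalability)
        out += [i for i in self.flagged_monotonicity if i not in out]
        return out


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    reference_eigenvalues: np.ndarray
    n_factors_retained: int
    method: str


# ---------------------------------------------------------------------------
# Loevinger H
# ---------------------------------------------------------------------------

def _pair_cov_covmax(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Observed covariance and its comonotonic maximum (same marginals).

    The maximal covariance for fixed marginals is attained when both variables
    are sorted in the same order (Hardy–Littlewood rearrangement), so
    ``cov_max`` is the covariance of the two independently sorted samples.
    """
    n = x.size
    cov = float(np.cov(x, y, ddof=0)[0, 1])
    xs = np.sort(x)
    ys = np.sort(y)
    cov_max = float(xs @ ys / n - xs.mean() * ys.mean())
    return cov, cov_max


def loevinger_coefficients(matrix: ResponseMatrix, keep_threshold: float = 0.30) -> MokkenResult:
    """Pairwise, item and scale Loevinger H from pairwise-complete data.

    Items whose H falls below ``keep_threshold`` are flagged for removal.
    Zero-variance items get an undefined (NaN) H and are reported as such.
    """
    if matrix.n_items < 2:
        raise ValueError("need at least 2 items")
    ids = matrix.item_ids
    k = matrix.n_items
    cov = np.full((k, k), np.nan)
    cov_max = np.full((k, k), np.nan)
    resp = matrix.responses
    for j in range(k):
        for l in range(j + 1, k):
            both = ~np.isnan(resp[:, j]) & ~np.isnan(resp[:, l])
            if both.sum() < 3:
                continue
            xj, xl = resp[both, j], resp[both, l]
            if xj.std() == 0 or xl.std() == 0:
                continue
            c, cm = _pair_cov_covmax(xj, xl)
            cov[j, l] = cov[l, j] = c
            cov_max[j, l] = cov_max[l, j] = cm
    result = MokkenResult()
    for j in range(k):
        for l in range(j + 1, k):
            if np.isfinite(cov[j, l]) and cov_max[j, l] > 0:
                result.pair_H[(ids[j], ids[l])] = cov[j, l] / cov_max[j, l]
    for j in range(k):
        num = np.nansum(np.delete(cov[j], j))
        den = np.nansum(np.delete(cov_max[j], j))
        has_any = np.isfinite(np.delete(cov[j], j)).any()
        result.item_H[ids[j]] = num / den if (has_any and den > 0) else np.nan
    triu = np.triu_indices(k, 1)
    num = np.nansum(cov[triu])
    den = np.nansum(cov_max[triu])
    result.scale_H = num / den if den > 0 else np.nan
    result.flagged_scalability = [
        i for i, h in result.item_H.items() if np.isfinite(h) and h < keep_threshold
    ]
    return result


# ---------------------------------------------------------------------------
# Monotonicity
# ---------------------------------------------------------------------------

def _rest_score(matrix: ResponseMatrix, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Rest score (total of the other items, rescaled for missingness).

    A person contributes if item ``j`` is observed and at least half of the
    remaining items are; partially missing rest totals are scaled up to the
    full rest-item count so they stay comparable.
    """
    resp = matrix.responses
    others = np.delete(np.arange(matrix.n_items), j)
    obs = ~np.isnan(resp[:, others])
    n_obs = obs.sum(axis=1)
    usable = (~np.isnan(resp[:, j])) & (n_obs >= max(1, len(others) // 2))
    totals = np.nansum(resp[:, others], axis=1)
    rest = np.where(n_obs > 0, totals * len(others) / np.maximum(n_obs, 1), 0.0)
    return rest[usable], np.nonzero(usable)[0]


def _restscore_groups(rest: np.ndarray, minsize: int) -> list[np.ndarray]:
    """Partition persons into ordered rest-score groups of size >= minsize.

    Persons sharing a rest-score value are never split across groups."""
    order = np.argsort(rest, kind="mergesort")
    groups: list[list[int]] = []
    current: list[int] = []
    sorted_rest = rest[order]
    for pos, idx in enumerate(order):
        current.append(idx)
        boundary = pos == len(order) - 1 or sorted_rest[pos + 1] != sorted_rest[pos]
        if len(current) >= minsize and boundary:
            groups.append(current)
            current = []
    if current:
        if groups:
            groups[-1].extend(current)
        else:
            groups.append(current)
    return [np.asarray(g) for g in groups]


def check_monotonicity(
    matrix: ResponseMatrix,
    minsize: int | None = None,
    alpha: float = 0.05,
    minvi: float = 0.03,
    minvi_flag: float = 0.08,
) -> MokkenResult:
    """Test monotonicity of each item's step curves over rest-score groups.

    For every step ``k`` the proportions ``P(X >= k)`` across ordered
    rest-score groups should be non-decreasing.  A decrease larger than
    ``minvi`` counts as a violation; it is *significant* if a one-sided
    two-proportion z-test rejects at ``alpha``.  An item is flagged when a
    significant violation is also material (at least ``minvi_flag`` deep) —
    the severity floor keeps chance wobbles in the flat tails of well-behaved
    step curves from flagging items.  Items without enough complete cases to
    form two groups are marked untestable.
    """
    if minsize is None:
        minsize = max(50, matrix.n_persons // 10)
    result = MokkenResult()
    for j, item_id in enumerate(matrix.item_ids):
        rest, persons = _rest_score(matrix, j)
        if rest.size < 2 * minsize:
            result.monotonicity[item_id] = {"testable": False, "n": int(rest.size)}
            continue
        groups = _restscore_groups(rest, minsize)
        if len(groups) < 2:
            result.monotonicity[item_id] = {"testable": False, "n": int(rest.size)}
            continue
        x = matrix.responses[persons, j]
        mc = int(matrix.max_cat[j])
        n_active = 0
        n_vi = 0
        n_sig = 0
        max_vi = 0.0
        for k in range(1, mc + 1):
            p = np.array([(x[g] >= k).mean() for g in groups])
            sizes = np.array([g.size for g in groups])
            n_groups = len(groups)
            for g in range(n_groups - 1):
                for h in range(g + 1, n_groups):  # all ordered group pairs
                    n_active += 1
                    diff = p[g] - p[h]  # positive = violation
                    if diff > minvi:
                        n_vi += 1
                        max_vi = max(max_vi, float(diff))
                        pool = (p[g] * sizes[g] + p[h] * sizes[h]) / (sizes[g] + sizes[h])
                        se = np.sqrt(pool * (1 - pool) * (1 / sizes[g] + 1 / sizes[h]))
                        if se > 0 and diff / se > stats.norm.ppf(1 - alpha) and diff >= minvi_flag:
                            n_sig += 1
        result.monotonicity[item_id] = {
            "testable": True,
            "n": int(rest.size),
            "n_groups": len(groups),
            "n_active_pairs": n_active,
            "n_violations": n_vi,
            "n_significant": n_sig,
            "max_violation": max_vi,
        }
        if n_sig > 0:
            result.flagged_monotonicity.append(item_id)
    return result


# ---------------------------------------------------------------------------
# Parallel analysis
# ---------------------------------------------------------------------------

def _correlation(resp: np.ndarray, method: str) -> np.ndarray:
    if method == "polychoric":
        return polychoric_matrix(resp)
    if method == "pearson":
        import pandas as pd

        r = pd.DataFrame(resp).corr(min_periods=3).to_numpy()
        r[~np.isfinite(r)] = 0.0
        np.fill_diagonal(r, 1.0)
        return r
    raise ValueError("method must be 'polychoric' or 'pearson'")


def parallel_analysis(
    matrix: ResponseMatrix,
    n_reference: int = 20,
    seed: int | None = None,
    method: str = "polychoric",
    percentile: float = 95.0,
) -> ParallelAnalysisResult:
    """Horn's parallel analysis of the item correlation matrix.

    Reference eigenvalues are the rank-wise ``percentile`` (default 95th, the
    usual Horn criterion; a mean-rule variant via ``percentile=50``) over
    ``n_reference`` datasets built by independently permuting each item's
    observed values, which preserves every marginal category distribution and
    the missingness pattern while destroying inter-item structure.
    Components are retained while the observed eigenvalue exceeds its
    reference at the same rank.
    """
    rng = np.random.default_rng(seed)
    resp = matrix.responses
    observed = np.sort(np.linalg.eigvalsh(_correlation(resp, method)))[::-1]
    refs = np.empty((n_reference, matrix.n_items))
    for b in range(n_reference):
        shuffled = resp.copy()
        for j in range(matrix.n_items):
            obs = ~np.isnan(shuffled[:, j])
            vals = shuffled[obs, j]
            shuffled[obs, j] = rng.permutation(vals)
        refs[b] = np.sort(np.linalg.eigvalsh(_correlation(shuffled, method)))[::-1]
    reference = np.percentile(refs, percentile, axis=0)
    n_retained = 0
    for o, r in zip(observed, reference):
        if o > r:
            n_retained += 1
        else:
            break
    return ParallelAnalysisResult(observed, reference, n_retained, method)


def mokken_screen(
    matrix: ResponseMatrix,
    keep_threshold: float = 0.30,
    minsize: int | None = None,
    alpha: float = 0.05,
) -> MokkenResult:
    """Combined scalability + monotonicity screen (shared result object)."""
    res = loevinger_coefficients(matrix, keep_threshold)
    mono = check_monotonicity(matrix, minsize=minsize, alpha=alpha)
    res.monotonicity = mono.monotonicity
    res.flagged_monotonicity = mono.flagged_monotonicity
    return res
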