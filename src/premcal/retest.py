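"""Test–retest reliability: paired correlation and Bland–Altman agreement."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .data_io import ThetaEstimate

__all__ = ["AgreementResult", "test_retest", "bland_altman_plot"]


@dataclass
class AgreementResult:
    n_pairs: int
    pearson_r: float
    p_value: float
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pct_within_loa: float
    diffs: np.ndarray = None
    means: np.ndarray = None


def _as_series(estimates) -> dict[str, float]:
    if isinstance(estimates, Mapping):
        return {str(k): float(v) for k, v in estimates.items()}
    if len(estimates) and isinstance(estimates[0], ThetaEstimate):
        return {e.person_id: e.theta for e in estimates}
    raise TypeError("pass ThetaEstimate sequences or person_id -> theta mappings")


def test_retest(theta_t1, theta_t2, loa_multiplier: float = 1.96) -> AgreementResult:
    """Pearson correlation and Bland–Altman limits of agreement for paired
    trait estimates (matched on person id; differences are t1 - t2).

    The limits of agreement are ``mean_diff ± 1.96 * sd_diff`` (sample SD,
    ddof=1).  With degenerate (zero-variance) differences every pair counts
    as within the limits; a zero-variance theta series makes the correlation
    undefined (NaN) and is reported as such rather than raising.
    """
    s1 = _as_series(theta_t1)
    s2 = _as_series(theta_t2)
    common = [pid for pid in s1 if pid in s2]
    if len(common) < 3:
        raise ValueError(f"need at least 3 matched pairs, found {len(common)}")
    x = np.array([s1[p] for p in common])
    y = np.array([s2[p] for p in common])
    if x.std() == 0 or y.std() == 0:
        r, p = np.nan, np.nan
    else:
        r, p = stats.pearsonr(x, y)
    d = x - y
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    loa_low = mean_diff - loa_multiplier * sd_diff
    loa_high = mean_diff + loa_multiplier * sd_diff
    if sd_diff == 0:
        pct = 100.0
    else:
        pct = float(((d >= loa_low) & (d <= loa_high)).mean() * 100)
    return AgreementResult(
        n_pairs=len(common),
        pearson_r=float(r),
        p_value=float(p),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=loa_low,
        loa_high=loa_high,
        pct_within_loa=pct,
        diffs=d,
        means=(x + y) / 2,
    )


def bland_altman_plot(result: AgreementResult, path=None, ax=None):
    """Scatter of pair means vs differences with the limits of agreement."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.7)
    ax.axhline(result.mean_diff, color="k", lw=1)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("Mean of occasions (theta)")
    ax.set_ylabel("Baseline - follow-up (theta)")
    ax.set_title(f"{result.pct_within_loa:.1f}% of pairs within limits of agreement")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
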