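"""Differential item functioning via hybrid ordinal regression / IRT.

For each item, three nested cumulative-logit (proportional-odds) models are
fitted to the observed item response:

* M0: item ~ theta_hat
* M1: item ~ theta_hat + group
* M2: item ~ theta_hat + group + theta_hat x group

Total DIF is the likelihood-ratio test of M2 against M0 (2 df), Bonferroni
corrected across items; uniform DIF is M1 vs M0.  Magnitude is the McFadden
pseudo-R-squared change ``R2(M2) - R2(M0)`` with ``R2 = 1 - ll / ll_null``
(thresholds-only null).  An item is flagged only when the corrected test is
significant AND the R2 change exceeds the meaningful-DIF cut (default .035).

The matching criterion purifies itself: items flagged in one round are
excluded from the trait estimate used in the next, until the flagged set
stabilises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ResponseMatrix
from .pcm import PCMModel, _eap_arrays

__all__ = ["DIFResult", "detect_dif", "dif_groups_from_metadata"]

USABLE_GROUPS = ("service_user", "carer")


@dataclass
class DIFResult:
    groups: tuple[str, str]
    items_: dict[str, dict] = field(default_factory=dict)
    n_purification_rounds: int = 0

    @property
    def flagged_items(self) -> list[str]:
        return [i for i, rec in self.items_.items() if rec.get("flagged")]


def dif_groups_from_metadata(matrix: ResponseMatrix) -> tuple[np.ndarray, int]:
    """Service-user vs carer contrast from the matrix group column.

    Persons labelled as both roles or unreported are excluded (returned label
    ``None``); the count of exclusions is reported.  Raises if fewer than two
    usable groups remain.
    """
    if matrix.group is None:
        raise ValueError("matrix has no group metadata")
    labels = np.array(
        [g if g in USABLE_GROUPS else None for g in matrix.group], dtype=object
    )
    n_excluded = int(sum(1 for g in labels if g is None))
    present = {g for g in labels if g is not None}
    if len(present) < 2:
        raise ValueError(f"fewer than 2 usable groups (found {sorted(map(str, present))})")
    return labels, n_excluded


def _ordinal_loglik_null(y: np.ndarray) -> float:
    """Log-likelihood of the thresholds-only cumulative-logit model, which
    reproduces the marginal category proportions exactly."""
    counts = np.bincount(y)
    counts = counts[counts > 0]
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum())


def _fit_ordinal(y: np.ndarray, exog: np.ndarray | None):
    """Fit a cumulative-logit model; returns (loglik, converged)."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    endog = pd.Series(pd.Categorical(y, ordered=True))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(endog, exog, distr="logit")
        res = model.fit(method="bfgs", maxiter=200, disp=False)
    converged = bool(res.mle_retvals.get("converged", True))
    return float(res.llf), converged


def _item_dif_tests(y: np.ndarray, theta: np.ndarray, g: np.ndarray) -> dict:
    """LR tests and McFadden R2 change for one item.

    ``g`` is a 0/1 group indicator.  Items whose regressions fail to converge
    (e.g. separation from an empty group x category cell) are reported as
    unstable rather than flagged.
    """
    if np.unique(y).size < 2:
        return {"unstable": True, "reason": "single observed category"}
    ll_null = _ordinal_loglik_null(np.unique(y, return_inverse=True)[1])
    x0 = theta[:, None]
    x1 = np.column_stack([theta, g])
    x2 = np.column_stack([theta, g, theta * g])
    try:
        ll0, c0 = _fit_ordinal(y, x0)
        ll1, c1 = _fit_ordinal(y, x1)
        ll2, c2 = _fit_ordinal(y, x2)
    except Exception as exc:  # separation / singular hessian
        return {"unstable": True, "reason": str(exc)}
    if not (c0 and c1 and c2):
        return {"unstable": True, "reason": "non-convergence"}
    lr_uniform = max(2.0 * (ll1 - ll0), 0.0)
    lr_total = max(2.0 * (ll2 - ll0), 0.0)
    r2 = lambda ll: 1.0 - ll / ll_null if ll_null != 0 else np.nan
    return {
        "unstable": False,
        "lr_chi2_uniform": lr_uniform,
        "p_uniform": float(stats.chi2.sf(lr_uniform, 1)),
        "lr_chi2_total": lr_total,
        "p_total": float(stats.chi2.sf(lr_total, 2)),
        "mcfadden_r2_change": max(r2(ll2) - r2(ll0), 0.0),
    }


def detect_dif(
    matrix: ResponseMatrix,
    group_labels: np.ndarray,
    model: PCMModel,
    alpha: float = 0.05,
    r2_threshold: float = 0.035,
    max_rounds: int = 10,
    min_n: int = 10,
) -> DIFResult:
    """Iterative hybrid ordinal-regression DIF scan over all bank items.

    The trait estimate entering the regressions is the EAP score; in each
    purification round it is re-computed from the currently unflagged items
    only, and the scan repeats until the flagged set stabilises (or
    ``max_rounds``).
    """
    labels = np.asarray(group_labels, dtype=object)
    usable = np.array([g is not None and g == g for g in labels])
    groups = sorted({str(g) for g in labels[usable]})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    g_num = np.where(labels == groups[1], 1.0, 0.0)
    counts = [(labels[usable] == g).sum() for g in groups]
    if min(counts) < min_n:
        raise ValueError(f"smallest group has {min(counts)} members (< {min_n})")

    item_ids = model.item_ids
    flagged: set[str] = set()
    result = DIFResult(groups=tuple(groups))
    for round_no in range(1, max_rounds + 1):
        anchor = [i for i in item_ids if i not in flagged] or item_ids
        anchor_model = PCMModel(
            model.bank.subset(anchor), model.prior_mean, model.prior_sd, model.quadrature
        )
        theta, _ = _eap_arrays(anchor_model, matrix.subset_items(anchor))
        bonf = alpha / len(item_ids)
        new_flagged: set[str] = set()
        records: dict[str, dict] = {}
        for iid in item_ids:
            col = matrix.column(iid)
            obs = usable & ~np.isnan(col)
            y = col[obs].astype(int)
            rec = _item_dif_tests(y, theta[obs], g_num[obs])
            if not rec.get("unstable"):
                rec["significant"] = rec["p_total"] < bonf
                rec["flagged"] = bool(rec["significant"] and rec["mcfadden_r2_change"] > r2_threshold)
                if rec["flagged"]:
                    new_flagged.add(iid)
            else:
                rec["flagged"] = False
            records[iid] = rec
        result.items_ = records
        result.n_purification_rounds = round_no
        if new_flagged == flagged:
            break
        flagged = new_flagged
    return result
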