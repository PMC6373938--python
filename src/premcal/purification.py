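"""Iterative item purification: threshold ordering, local dependency, misfit.

The pipeline mirrors the item-reduction sequence used to develop the measure:

1. non-parametric screen (monotonicity violations, low Loevinger H);
2. parallel-analysis gate for unidimensionality;
3. PCM calibration;
4. category-threshold-disorder diagnosis and uniform rescoring, then refit;
5. Yen's Q3 local-dependency detection and removal, then refit;
6. differential item functioning between respondent groups, then refit;
7. item-misfit removal (worst first, refitting between removals).

Every action lands in a :class:`~premcal.data_io.PurificationLedger` entry
with the statistic that triggered it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ItemBank, PurificationLedger, ResponseMatrix
from . import dif as dif_mod
from .mokken import mokken_screen, parallel_analysis
from .pcm import (
    PCMModel,
    _eap_arrays,
    category_probabilities,
    fit_pcm,
    fit_statistics,
    impute_missing,
    item_information,
)

__all__ = [
    "LDReport",
    "PurifyConfig",
    "MultidimensionalityError",
    "detect_threshold_disorder",
    "rescore_items",
    "q3_local_dependency",
    "resolve_local_dependency",
    "remove_misfitting_items",
    "run_purification_pipeline",
]


class MultidimensionalityError(RuntimeError):
    """Parallel analysis retained more than one component; halt the pipeline."""


@dataclass
class LDReport:
    item_ids: list[str]
    q3: np.ndarray  # symmetric, NaN diagonal
    threshold: float
    average_residual_corr: float
    dependent_pairs: list[tuple[str, str]]
    uncomputable_pairs: list[tuple[str, str]] = field(default_factory=list)

    def partners(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {i: set() for i in self.item_ids}
        for a, b in self.dependent_pairs:
            out[a].add(b)
            out[b].add(a)
        return out


# ---------------------------------------------------------------------------
# Threshold ordering
# ---------------------------------------------------------------------------

def detect_threshold_disorder(model: PCMModel, grid_step: float = 0.01, span: float = 10.0) -> dict[str, dict]:
    """Per-item ordered/disordered verdicts.

    Two equivalent diagnostics are computed and cross-checked: (a) scan a
    fine theta grid for categories that are never the modal response, and
    (b) check the adjacent-category thresholds for non-ascending values
    (``delta_h >= delta_{h+1}``), which for the PCM is the same condition.
    """
    grid = np.arange(-span, span + grid_step, grid_step)
    out = {}
    for it in model.bank:
        deltas = np.asarray(it.deltas)
        p = category_probabilities(deltas, grid)
        modal = np.unique(p.argmax(axis=1))
        never_modal = sorted(set(range(deltas.size + 1)) - set(modal.tolist()))
        disordered_grid = bool(never_modal)
        disordered_delta = bool((np.diff(deltas) <= 0).any()) if deltas.size > 1 else False
        # the two diagnoses coincide for the PCM, except that the grid scan
        # cannot resolve modal intervals narrower than its step
        resolvable = deltas.size < 2 or np.diff(deltas).min() > 2 * grid_step
        if resolvable and disordered_grid != disordered_delta:  # pragma: no cover
            raise AssertionError(
                f"threshold-disorder diagnostics disagree for item {it.item_id!r}"
            )
        out[it.item_id] = {
            "disordered": disordered_delta,
            "never_modal_categories": never_modal,
            "deltas": list(map(float, deltas)),
        }
    return out


def rescore_items(matrix: ResponseMatrix, scoring_map) -> ResponseMatrix:
    """Apply a non-decreasing raw-to-scored category map to every item.

    ``scoring_map`` is a sequence like ``(0, 1, 1, 2, 2)``.  Adjacent raw
    categories may share a score (collapsing); non-adjacent merges are
    impossible by construction since the map is non-decreasing and starts at
    zero.  Missingness is preserved.
    """
    sm = np.asarray(scoring_map, dtype=int)
    if sm[0] != 0 or (np.diff(sm) < 0).any() or (np.diff(sm) > 1).any():
        raise ValueError("scoring map must be non-decreasing, surjective and start at 0")
    out = matrix.copy()
    resp = out.responses
    obs = ~np.isnan(resp)
    if resp[obs].size and resp[obs].max() > sm.size - 1:
        bad = int(resp[obs].max())
        raise ValueError(f"raw category {bad} outside scoring map domain 0..{sm.size - 1}")
    resp[obs] = sm[resp[obs].astype(int)]
    new_max = np.minimum(matrix.max_cat, sm.size - 1)
    new_max = np.array([sm[m] for m in new_max])
    return ResponseMatrix(resp, out.person_ids, out.item_ids, new_max, out.group)


# ---------------------------------------------------------------------------
# Local dependency (Yen's Q3)
# ---------------------------------------------------------------------------

def q3_local_dependency(
    model: PCMModel,
    matrix: ResponseMatrix,
    offset: float = 0.2,
    mode: str = "impute",
) -> LDReport:
    """Residual correlations between items, flagged above an adaptive cut.

    Residuals are ``x_pi - E[X_i | theta_hat_p]`` with EAP theta estimates.
    The flagging threshold is ``offset`` plus the average off-diagonal
    residual correlation.  ``mode='impute'`` (default) completes the matrix by
    modal IRT imputation first; ``mode='pairwise'`` uses pairwise-complete
    cells instead.
    """
    if mode not in ("impute", "pairwise"):
        raise ValueError("mode must be 'impute' or 'pairwise'")
    work = impute_missing(model, matrix) if mode == "impute" else matrix
    theta, _ = _eap_arrays(model, work)
    ids = model.item_ids
    k = len(ids)
    resid = np.full((work.n_persons, k), np.nan)
    for j, it in enumerate(model.bank):
        x = work.column(it.item_id)
        p = category_probabilities(it.deltas, theta)
        expected = p @ np.arange(p.shape[1])
        resid[:, j] = x - expected
    q3 = np.full((k, k), np.nan)
    uncomputable = []
    for a in range(k):
        for b in range(a + 1, k):
            both = ~np.isnan(resid[:, a]) & ~np.isnan(resid[:, b])
            ra, rb = resid[both, a], resid[both, b]
            if both.sum() < 3 or ra.std() == 0 or rb.std() == 0:
                uncomputable.append((ids[a], ids[b]))
                continue
            q3[a, b] = q3[b, a] = float(np.corrcoef(ra, rb)[0, 1])
    triu = q3[np.triu_indices(k, 1)]
    avg = float(np.nanmean(triu)) if np.isfinite(triu).any() else 0.0
    threshold = offset + avg
    pairs = [
        (ids[a], ids[b])
        for a in range(k)
        for b in range(a + 1, k)
        if np.isfinite(q3[a, b]) and q3[a, b] > threshold
    ]
    return LDReport(list(ids), q3, threshold, avg, pairs, uncomputable)


def _integrated_information(model: PCMModel, item_id: str) -> float:
    """Item information integrated against the calibration prior."""
    it = model.bank.get(item_id)
    q = model.quadrature
    return float(q.weights @ item_information(it.deltas, q.nodes))


def resolve_local_dependency(report: LDReport, model: PCMModel) -> list[dict]:
    """Removal plan for locally dependent items.

    Items dependent on two or more partners are removed first (highest
    partner count first, ties broken by lower integrated information),
    recomputing partner counts after each removal.  Each surviving isolated
    pair then loses its less informative member.
    """
    partners = {i: set(p) for i, p in report.partners().items()}
    plan: list[dict] = []

    def info(i):
        return _integrated_information(model, i)

    while True:
        multi = {i: p for i, p in partners.items() if len(p) >= 2}
        if not multi:
            break
        victim = max(multi, key=lambda i: (len(partners[i]), -info(i), i))
        plan.append(
            {
                "item_id": victim,
                "reason": "locally dependent with multiple items",
                "n_partners": len(partners[victim]),
                "partners": sorted(partners[victim]),
                "integrated_information": info(victim),
            }
        )
        for p in partners.pop(victim):
            partners[p].discard(victim)
    seen = set()
    for a, b in sorted((tuple(sorted((i, next(iter(p))))) for i, p in partners.items() if p)):
        if (a, b) in seen:
            continue
        seen.add((a, b))
        ia, ib = info(a), info(b)
        victim, keeper = (a, b) if ia <= ib else (b, a)
        plan.append(
            {
                "item_id": victim,
                "reason": "isolated locally dependent pair; lower information",
                "partners": [keeper],
                "integrated_information": min(ia, ib),
                "partner_information": max(ia, ib),
            }
        )
    return plan


# ---------------------------------------------------------------------------
# Misfit removal
# ---------------------------------------------------------------------------

def remove_misfitting_items(
    model: PCMModel,
    matrix: ResponseMatrix,
    alpha: float | None = None,
    ledger: PurificationLedger | None = None,
    **fit_kw,
) -> tuple[PCMModel, ResponseMatrix]:
    """Remove items whose fit chi-square rejects, worst first, refitting
    between removals.

    ``alpha`` defaults to a Bonferroni-adjusted 0.05 across the current item
    count.  Raises if removal would leave fewer than two items.
    """
    ledger = ledger if ledger is not None else PurificationLedger()
    while True:
        k = len(model.bank)
        cut = alpha if alpha is not None else 0.05 / k
        if cut <= 0:
            return model, matrix
        report = fit_statistics(model, matrix)
        worst_id, worst_p = None, 1.0
        for iid, f in report.item_fit.items():
            if np.isfinite(f.get("p", np.nan)) and f["p"] < min(cut, worst_p):
                worst_id, worst_p = iid, f["p"]
        if worst_id is None:
            return model, matrix
        if k <= 2:
            raise RuntimeError("misfit removal would leave fewer than 2 items")
        ledger.add(
            "misfit",
            worst_id,
            "remove",
            {"chi2": report.item_fit[worst_id]["chi2"], "df": report.item_fit[worst_id]["df"], "p": worst_p, "alpha": cut},
            "item-fit chi-square below alpha",
        )
        keep = [i for i in model.item_ids if i != worst_id]
        matrix = matrix.subset_items(keep)
        model = fit_pcm(matrix, **fit_kw)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PurifyConfig:
    h_keep_threshold: float = 0.30
    mono_minsize: int | None = None
    mono_alpha: float = 0.05
    pa_n_reference: int = 20
    pa_method: str = "polychoric"
    rescore_map: tuple[int, ...] = (0, 1, 1, 2, 2)
    q3_offset: float = 0.2
    q3_mode: str = "impute"
    dif_enabled: bool = True
    dif_alpha: float = 0.05
    dif_r2_threshold: float = 0.035
    misfit_alpha: float | None = None  # None = Bonferroni 0.05/k
    n_nodes: int = 61
    em_tol: float = 1e-4
    seed: int = 0


def run_purification_pipeline(
    matrix: ResponseMatrix,
    config: PurifyConfig | None = None,
) -> tuple[ItemBank, PurificationLedger, PCMModel]:
    """Run the full item-reduction sequence; returns (bank, ledger, model)."""
    cfg = config or PurifyConfig()
    ledger = PurificationLedger()
    fit_kw = dict(n_nodes=cfg.n_nodes, tol=cfg.em_tol)
    applied_rescore: tuple[int, ...] | None = None

    # 1. non-parametric screen
    screen = mokken_screen(matrix, cfg.h_keep_threshold, cfg.mono_minsize, cfg.mono_alpha)
    ledger.add(
        "mokken",
        (),
        "flag" if screen.flagged_items else "keep",
        {"scale_H": None if not np.isfinite(screen.scale_H) else float(screen.scale_H),
         "n_flagged": len(screen.flagged_items)},
        "scalability and monotonicity screen",
    )
    for iid in screen.flagged_monotonicity:
        ledger.add("mokken", iid, "remove", screen.monotonicity.get(iid, {}), "monotonicity violation")
    for iid in screen.flagged_scalability:
        if iid in ledger.removed_items():
            continue
        ledger.add("mokken", iid, "remove", {"item_H": screen.item_H[iid]}, f"item H below {cfg.h_keep_threshold}")
    keep = [i for i in matrix.item_ids if i not in ledger.removed_items()]
    work = matrix.subset_items(keep)

    # 2. dimensionality gate
    pa = parallel_analysis(work, cfg.pa_n_reference, seed=cfg.seed, method=cfg.pa_method)
    ledger.add(
        "parallel_analysis",
        (),
        "keep",
        {
            "n_factors_retained": pa.n_factors_retained,
            "observed_eigenvalues": [float(v) for v in pa.observed_eigenvalues[:3]],
            "reference_eigenvalues": [float(v) for v in pa.reference_eigenvalues[:3]],
        },
        "unidimensionality check",
    )
    if pa.n_factors_retained > 1:
        raise MultidimensionalityError(
            f"parallel analysis retained {pa.n_factors_retained} components; "
            "the scale is not unidimensional"
        )

    # 3. initial calibration
    model = fit_pcm(work, **fit_kw)

    # 4. threshold ordering -> uniform rescoring
    verdicts = detect_threshold_disorder(model)
    disordered = [i for i, v in verdicts.items() if v["disordered"]]
    if disordered:
        max_raw = int(work.max_cat.max())
        sm = tuple(cfg.rescore_map)[: max_raw + 1]
        work = rescore_items(work, sm)
        applied_rescore = sm
        ledger.add(
            "rescore",
            tuple(work.item_ids),
            "rescore",
            {"disordered_items": disordered, "scoring_map": list(sm)},
            "single rescoring solution applied to all items",
        )
        model = fit_pcm(work, **fit_kw)
    else:
        ledger.add("rescore", (), "keep", {"disordered_items": []}, "all category thresholds ordered")

    # 5. local dependency
    ld = q3_local_dependency(model, work, offset=cfg.q3_offset, mode=cfg.q3_mode)
    ledger.add(
        "local_dependency",
        (),
        "flag",
        {"n_dependent_pairs": len(ld.dependent_pairs), "threshold": ld.threshold,
         "average_residual_corr": ld.average_residual_corr},
        "Yen's Q3 screen",
    )
    for step in resolve_local_dependency(ld, model):
        ledger.add("local_dependency", step["item_id"], "remove", step, step["reason"])
    removed = ledger.removed_items()
    if any(i in removed for i in work.item_ids):
        work = work.subset_items([i for i in work.item_ids if i not in removed])
        model = fit_pcm(work, **fit_kw)

    # 6. differential item functioning
    if cfg.dif_enabled and work.group is not None:
        try:
            labels, excluded = dif_mod.dif_groups_from_metadata(work)
        except ValueError as exc:
            ledger.add("dif", (), "keep", {}, f"DIF skipped: {exc}")
            labels = None
        if labels is not None:
            dif_res = dif_mod.detect_dif(
                work, labels, model, alpha=cfg.dif_alpha, r2_threshold=cfg.dif_r2_threshold
            )
            flagged = [i for i, rec in dif_res.items_.items() if rec["flagged"]]
            ledger.add(
                "dif",
                (),
                "flag",
                {"n_flagged": len(flagged), "n_excluded_persons": excluded,
                 "n_rounds": dif_res.n_purification_rounds},
                "hybrid ordinal regression DIF scan",
            )
            for iid in flagged:
                rec = dif_res.items_[iid]
                ledger.add(
                    "dif",
                    iid,
                    "remove",
                    {"lr_chi2_total": rec["lr_chi2_total"], "p": rec["p_total"],
                     "mcfadden_r2_change": rec["mcfadden_r2_change"]},
                    "significant DIF with meaningful McFadden R2 change",
                )
            if flagged:
                work = work.subset_items([i for i in work.item_ids if i not in set(flagged)])
                model = fit_pcm(work, **fit_kw)
    elif cfg.dif_enabled:
        ledger.add("dif", (), "keep", {}, "DIF skipped: no group metadata")

    # 7. misfit removal with refits
    model, work = remove_misfitting_items(model, work, alpha=cfg.misfit_alpha, ledger=ledger, **fit_kw)

    ledger.add(
        "final",
        tuple(work.item_ids),
        "keep",
        {"n_items": len(work.item_ids), "loglik": model.loglik,
         "scoring_map": list(applied_rescore) if applied_rescore else None},
        "final calibrated bank",
    )
    # attach the applied raw-to-scored map so the bank can score raw data
    if applied_rescore is not None:
        from .data_io import Item

        bank = ItemBank(
            [
                Item(it.item_id, it.label, it.deltas, applied_rescore)
                if len(it.deltas) == max(applied_rescore)
                else it  # a fit-time category merge changed this item's range
                for it in model.bank
            ]
        )
        model = PCMModel(bank, model.prior_mean, model.prior_sd, model.quadrature,
                         loglik=model.loglik, loglik_trace=model.loglik_trace,
                         n_iterations=model.n_iterations, merge_log=model.merge_log)
    return model.bank, ledger, model
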