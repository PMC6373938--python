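"""Partial credit Rasch model: probabilities, calibration, scoring, fit.

The partial credit model (PCM) gives the probability of scored category
``k`` of an item with thresholds ``delta_1..delta_M`` at trait level theta as

    P(X = k | theta) = exp(sum_{h<=k} (theta - delta_h)) / sum_m exp(...)

with the empty sum equal to 0.  Thresholds are calibrated by marginal maximum
likelihood (Bock–Aitkin EM over a fixed quadrature grid with a standard-normal
latent prior for identification).  Persons are scored by the Bayesian expected
a posteriori (EAP) estimator: posterior mean with the posterior standard
deviation as the reported SE.

Item information under the PCM is the conditional category variance
``Var(X | theta)``, which equals the negative second derivative of the
log-likelihood expectation; test information is the sum over items.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .data_io import Item, ItemBank, ResponseMatrix, ThetaEstimate

__all__ = [
    "Quadrature",
    "PCMModel",
    "FitReport",
    "category_probabilities",
    "item_information",
    "test_information",
    "fit_pcm",
    "eap_score",
    "eap_scores",
    "fit_statistics",
    "marginal_reliability",
    "impute_missing",
]

log = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_deltas=None):
        super().__init__(message)
        self.last_deltas = last_deltas


# ---------------------------------------------------------------------------
# Probabilities and information
# ---------------------------------------------------------------------------

def category_probabilities(deltas: Sequence[float], theta) -> np.ndarray:
    """PCM category probabilities; shape ``theta.shape + (n_categories,)``.

    Numerically stabilised by max-subtraction, so arbitrarily extreme theta
    values are safe.
    """
    deltas = np.asarray(deltas, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n_cat = deltas.size + 1
    # cumulative logit of category k: k*theta - sum_{h<=k} delta_h
    cum_delta = np.concatenate([[0.0], np.cumsum(deltas)])
    s = theta[..., None] * np.arange(n_cat) - cum_delta
    s -= s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def item_information(deltas: Sequence[float], theta) -> np.ndarray:
    """PCM item information ``Var(X | theta)``."""
    p = category_probabilities(deltas, theta)
    k = np.arange(p.shape[-1], dtype=float)
    m1 = p @ k
    m2 = p @ (k**2)
    return m2 - m1**2


def test_information(bank: ItemBank, theta) -> np.ndarray:
    """Test information: sum of item informations."""
    theta = np.asarray(theta, dtype=float)
    out = np.zeros(theta.shape)
    for it in bank:
        out = out + item_information(it.deltas, theta)
    return out


# ---------------------------------------------------------------------------
# Quadrature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Quadrature:
    """Fixed rectangular quadrature with normalised prior weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w / w.sum())

    @classmethod
    def gaussian(cls, mean: float = 0.0, sd: float = 1.0, n_nodes: int = 61, span: float = 6.0) -> "Quadrature":
        """Evenly spaced nodes on ``mean ± span`` (theta units when sd=1) with
        normal-density weights.  ``span`` is in theta units, not SD units."""
        nodes = np.linspace(mean - span, mean + span, n_nodes)
        return cls(nodes, stats.norm.pdf(nodes, mean, sd))

    @classmethod
    def for_prior(cls, mean: float, sd: float, n_nodes: int = 81, span_sd: float = 4.0) -> "Quadrature":
        """Nodes covering ``mean ± span_sd * sd`` with normal weights."""
        nodes = np.linspace(mean - span_sd * sd, mean + span_sd * sd, n_nodes)
        return cls(nodes, stats.norm.pdf(nodes, mean, sd))


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class PCMModel:
    """A calibrated (or externally supplied) PCM item bank plus scoring prior."""

    bank: ItemBank
    prior_mean: float = 0.0
    prior_sd: float = 1.0
    quadrature: Quadrature = None
    loglik: float = np.nan
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    merge_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.quadrature is None:
            self.quadrature = Quadrature.gaussian(self.prior_mean, self.prior_sd)

    @property
    def item_ids(self) -> list[str]:
        return self.bank.item_ids

    def log_prob_grid(self) -> list[np.ndarray]:
        """Per item: log P(X=k | node), shape (n_nodes, n_categories)."""
        return [np.log(category_probabilities(it.deltas, self.quadrature.nodes)) for it in self.bank]

    @classmethod
    def from_bank(cls, bank: ItemBank, prior_mean: float = 0.0, prior_sd: float = 1.0, **kw) -> "PCMModel":
        return cls(bank=bank, prior_mean=prior_mean, prior_sd=prior_sd, **kw)


def _encode(matrix: ResponseMatrix) -> np.ndarray:
    """Responses as int array with -1 for missing."""
    x = matrix.responses.copy()
    x[np.isnan(x)] = -1
    return x.astype(int)


def _person_loglik_grid(model: PCMModel, x: np.ndarray) -> np.ndarray:
    """Log-likelihood of each person's observed responses at each node.

    ``x``: int array (n_persons, n_items), -1 missing, columns aligned with
    the model bank.  Missing responses contribute nothing.
    """
    n, k = x.shape
    grid = model.quadrature.nodes
    ll = np.zeros((n, grid.size))
    for j, logp in enumerate(model.log_prob_grid()):
        obs = x[:, j] >= 0
        if obs.any():
            ll[obs] += logp[:, x[obs, j]].T
    return ll


def _posterior(model: PCMModel, ll: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalised posterior over nodes and the marginal log-likelihood."""
    w = model.quadrature.weights
    a = ll.max(axis=1, keepdims=True)
    joint = np.exp(ll - a) * w
    norm = joint.sum(axis=1, keepdims=True)
    marg_ll = float((np.log(norm) + a).sum())
    return joint / norm, marg_ll


# ---------------------------------------------------------------------------
# Calibration (Bock–Aitkin EM-MML)
# ---------------------------------------------------------------------------

def _merge_unobserved_categories(matrix: ResponseMatrix) -> tuple[np.ndarray, list[list[int]], list[dict]]:
    """Recode each item so every category 0..max is observed.

    Unobserved categories are merged downward into their lower neighbour
    (upward for an unobserved category 0); the action is logged.  Returns the
    recoded responses, the per-item recode maps (raw scored code -> model
    code) and the log.
    """
    x = _encode(matrix)
    maps: list[list[int]] = []
    logs: list[dict] = []
    for j in range(matrix.n_items):
        mc = int(matrix.max_cat[j])
        col = x[:, j]
        observed = set(col[col >= 0].tolist())
        recode, nxt = [], -1
        for c in range(mc + 1):
            if c in observed:
                nxt += 1
            recode.append(max(nxt, 0))
        if len(observed) < mc + 1:
            logs.append(
                {
                    "item_id": matrix.item_ids[j],
                    "unobserved": sorted(set(range(mc + 1)) - observed),
                    "recode_map": list(recode),
                }
            )
        maps.append(recode)
        lut = np.asarray(recode)
        obs = col >= 0
        x[obs, j] = lut[col[obs]]
    return x, maps, logs


def _item_neg_loglik_and_grad(deltas: np.ndarray, nodes: np.ndarray, r: np.ndarray):
    """Expected complete-data negative log-likelihood of one item and gradient.

    ``r``: expected counts, shape (n_nodes, n_categories).
    d log P_k / d delta_h = P(X >= h) - 1[k >= h].
    """
    p = category_probabilities(deltas, nodes)
    f = -float(np.sum(r * np.log(np.clip(p, 1e-300, None))))
    n_cat = p.shape[-1]
    # survival P(X >= h) for h = 1..n_cat-1
    surv = 1.0 - p.cumsum(axis=-1)[:, :-1]  # (nodes, M)
    row_tot = r.sum(axis=1)  # (nodes,)
    # sum_k r_qk * 1[k >= h] = sum_{k>=h} r_qk
    upper = r[:, ::-1].cumsum(axis=1)[:, ::-1]  # upper[:, h] = sum_{k>=h} r
    grad = -(surv * row_tot[:, None] - upper[:, 1:]).sum(axis=0)
    return f, grad


def _init_deltas(x: np.ndarray, j: int, n_cat: int) -> np.ndarray:
    """Adjacent-category log-odds start values from observed frequencies."""
    col = x[:, j]
    col = col[col >= 0]
    counts = np.bincount(col, minlength=n_cat).astype(float) + 0.5
    return np.log(counts[:-1] / counts[1:])


def fit_pcm(
    matrix: ResponseMatrix,
    n_nodes: int = 61,
    span: float = 6.0,
    tol: float = 1e-4,
    max_iter: int = 500,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
    estimate_latent_sd: bool = True,
) -> PCMModel:
    """Calibrate PCM thresholds by EM marginal maximum likelihood.

    The latent location is fixed at ``prior_mean`` (default 0) for
    identification; because the slope is fixed at 1, the latent *scale* is a
    genuine parameter, so the prior SD is estimated alongside the thresholds
    by default (set ``estimate_latent_sd=False`` to pin it).  Missing
    responses are simply absent from the likelihood.  Convergence is declared
    when the largest parameter change falls below ``tol``; the marginal
    log-likelihood is recorded each iteration and is non-decreasing up to the
    inner-maximisation tolerance.
    """
    if matrix.n_items < 2:
        raise ValueError("need at least 2 items to calibrate")
    x, recode_maps, merge_logs = _merge_unobserved_categories(matrix)
    n_cats = [int(x[:, j].max()) + 1 for j in range(matrix.n_items)]
    for j, nc in enumerate(n_cats):
        if nc < 2:
            raise ValueError(f"item {matrix.item_ids[j]!r} has a single observed category")

    sd = float(prior_sd)
    nodes = np.linspace(prior_mean - span, prior_mean + span, n_nodes)
    deltas = [_init_deltas(x, j, nc) for j, nc in enumerate(n_cats)]
    # model bank items carry identity scoring over the *model* categories
    def build_model(loglik=np.nan, trace=None, n_iter=0):
        items = []
        for j, it_id in enumerate(matrix.item_ids):
            items.append(Item(it_id, "", tuple(deltas[j]), tuple(range(n_cats[j]))))
        quad = Quadrature(nodes, stats.norm.pdf(nodes, prior_mean, sd))
        return PCMModel(
            ItemBank(items), prior_mean, sd, quad,
            loglik=loglik, loglik_trace=list(trace or []), n_iterations=n_iter,
            merge_log=list(merge_logs),
        )

    # one-hot response indicators per item for fast expected counts
    indicators = []
    for j, nc in enumerate(n_cats):
        obs = x[:, j] >= 0
        ind = np.zeros((matrix.n_persons, nc))
        ind[np.nonzero(obs)[0], x[obs, j]] = 1.0
        indicators.append(ind)

    trace: list[float] = []
    for iteration in range(1, max_iter + 1):
        model = build_model()
        ll = _person_loglik_grid(model, x)
        post, marg = _posterior(model, ll)
        trace.append(marg)
        max_change = 0.0
        for j in range(matrix.n_items):
            r = post.T @ indicators[j]  # (nodes, n_cat)
            res = optimize.minimize(
                _item_neg_loglik_and_grad,
                deltas[j],
                args=(nodes, r),
                jac=True,
                method="L-BFGS-B",
            )
            new = res.x
            max_change = max(max_change, float(np.max(np.abs(new - deltas[j]))))
            deltas[j] = new
        if estimate_latent_sd:
            # EM update of the latent scale (location stays fixed at prior_mean)
            e_theta2 = float((post @ (nodes - prior_mean) ** 2).mean())
            new_sd = float(np.sqrt(np.clip(e_theta2, 0.01, 25.0)))
            max_change = max(max_change, abs(new_sd - sd))
            sd = new_sd
        if max_change < tol:
            model = build_model(loglik=trace[-1], trace=trace, n_iter=iteration)
            return model
    raise ConvergenceError(
        f"EM did not converge in {max_iter} iterations (last max |change| = {max_change:.2e})",
        last_deltas=deltas,
    )


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------

def _responses_to_array(model: PCMModel, responses) -> np.ndarray:
    """Accept a mapping item_id -> category or an aligned sequence (None/NaN missing)."""
    k = len(model.bank)
    if isinstance(responses, Mapping):
        out = np.full(k, -1, dtype=int)
        ids = model.item_ids
        for key, val in responses.items():
            out[ids.index(str(key))] = int(val)
    else:
        out = np.asarray(
            [-1 if (v is None or (isinstance(v, float) and np.isnan(v))) else int(v) for v in responses],
            dtype=int,
        )
        if out.size != k:
            raise ValueError("response vector length does not match bank size")
    for j, v in enumerate(out):
        if v >= 0 and v > len(model.bank.items[j].deltas):
            raise ValueError(
                f"category {v} out of range for item {model.item_ids[j]!r}"
            )
    return out


def eap_score(model: PCMModel, responses, person_id: str = "person") -> ThetaEstimate:
    """EAP trait estimate for one person.

    With zero observed responses the posterior is the prior, so the estimate
    is (prior_mean, prior_sd).
    """
    x = _responses_to_array(model, responses)[None, :]
    ll = _person_loglik_grid(model, x)
    post, _ = _posterior(model, ll)
    nodes = model.quadrature.nodes
    m = float(post[0] @ nodes)
    v = float(post[0] @ nodes**2 - m**2)
    return ThetaEstimate(person_id, m, float(np.sqrt(max(v, 1e-300))), int((x >= 0).sum()))


def score_responses(bank: ItemBank, matrix: ResponseMatrix) -> ResponseMatrix:
    """Map raw response categories onto each item's scored categories.

    Applies every bank item's ``scoring_map`` (e.g. the 0-1-1-2-2 collapse) to
    the corresponding matrix column; columns already on the scored metric
    (identity map) pass through unchanged.  Missingness is preserved.
    """
    out = matrix.subset_items(bank.item_ids)
    resp = out.responses
    new_max = out.max_cat.copy()
    for j, it in enumerate(bank):
        sm = np.asarray(it.scoring_map)
        col = resp[:, j]
        obs = ~np.isnan(col)
        if obs.any() and col[obs].max() > it.max_raw_category:
            raise ValueError(
                f"item {it.item_id!r}: raw category {int(col[obs].max())} outside "
                f"scoring map domain 0..{it.max_raw_category}"
            )
        resp[obs, j] = sm[col[obs].astype(int)]
        new_max[j] = len(it.deltas)
    return ResponseMatrix(resp, out.person_ids, out.item_ids, new_max, out.group)


def eap_scores(model: PCMModel, matrix: ResponseMatrix) -> list[ThetaEstimate]:
    """Vectorised EAP scoring of a whole response matrix."""
    theta, se = _eap_arrays(model, matrix)
    n_used = matrix.mask.sum(axis=1)
    return [
        ThetaEstimate(pid, float(t), float(s), int(n))
        for pid, t, s, n in zip(matrix.person_ids, theta, se, n_used)
    ]


def _eap_arrays(model: PCMModel, matrix: ResponseMatrix) -> tuple[np.ndarray, np.ndarray]:
    order = [matrix.item_index(i) for i in model.item_ids]
    x = _encode(matrix)[:, order]
    for j, it in enumerate(model.bank):
        if x[:, j].max() > len(it.deltas):
            raise ValueError(
                f"item {it.item_id!r}: category {int(x[:, j].max())} exceeds the "
                f"model's scored range 0..{len(it.deltas)}; score the raw matrix first"
            )
    ll = _person_loglik_grid(model, x)
    post, _ = _posterior(model, ll)
    nodes = model.quadrature.nodes
    m = post @ nodes
    v = post @ nodes**2 - m**2
    return m, np.sqrt(np.clip(v, 1e-300, None))


# ---------------------------------------------------------------------------
# Reliability and fit
# ---------------------------------------------------------------------------

def marginal_reliability(
    bank: ItemBank,
    mean: float = 0.0,
    sd: float = 1.0,
    n_nodes: int = 61,
    span_sd: float = 6.0,
) -> float:
    """Population marginal reliability ``(V - E[SE^2(theta)]) / V``.

    The conditional error variance is ``1 / I(theta)`` from test information,
    integrated over a Normal(mean, sd) population by quadrature.
    """
    quad = Quadrature.for_prior(mean, sd, n_nodes, span_sd)
    info = test_information(bank, quad.nodes)
    e_se2 = float(quad.weights @ (1.0 / info))
    v = sd**2
    return (v - e_se2) / v


@dataclass
class FitReport:
    model_chi2: float
    model_df: int
    model_p: float
    rmsea: float
    rmsea_ci: tuple[float, float]
    item_fit: dict[str, dict]
    marginal_reliability: float
    merge_log: list = field(default_factory=list)


def _item_fit_chi2(model: PCMModel, x: np.ndarray, ll: np.ndarray, j: int, n_strata: int):
    """Pearson chi-square of observed vs expected category counts in trait strata.

    To keep the statistic calibrated, the item under test is excluded from the
    trait information used against it: persons are stratified by their
    rest-EAP (posterior excluding item ``j``) and expected category counts are
    obtained by integrating the item's category probabilities over each
    person's rest posterior, rather than plugging in a point estimate.
    Adjacent strata are merged until every expected cell count is at least 5.
    """
    nodes, w = model.quadrature.nodes, model.quadrature.weights
    deltas = model.bank.items[j].deltas
    n_cat = len(deltas) + 1
    obs_mask = x[:, j] >= 0
    resp = x[obs_mask, j]
    if resp.size < 2 * n_cat:
        return {"chi2": np.nan, "df": 0, "p": np.nan, "n_strata": 0}
    logp_j = np.log(category_probabilities(deltas, nodes))  # (Q, K)
    ll_rest = ll[obs_mask] - logp_j[:, resp].T
    a = ll_rest.max(axis=1, keepdims=True)
    post = np.exp(ll_rest - a) * w
    post /= post.sum(axis=1, keepdims=True)
    t = post @ nodes  # rest-EAP, stratification variable only
    # per-person expected category probabilities under the rest posterior
    p_exp = post @ np.exp(logp_j)  # (n, K)
    edges = np.quantile(t, np.linspace(0, 1, n_strata + 1)[1:-1])
    strata = np.searchsorted(edges, t)
    groups = [np.nonzero(strata == g)[0] for g in range(n_strata)]
    groups = [g for g in groups if g.size]
    merged = True
    while merged and len(groups) > 1:
        merged = False
        for gi, g in enumerate(groups):
            if p_exp[g].sum(axis=0).min() < 5:
                other = gi - 1 if gi > 0 else gi + 1
                groups[other] = np.concatenate([groups[other], g])
                del groups[gi]
                merged = True
                break
    chi2 = 0.0
    for g in groups:
        exp = p_exp[g].sum(axis=0)
        obs = np.bincount(resp[g], minlength=n_cat).astype(float)
        chi2 += float(((obs - exp) ** 2 / np.clip(exp, 1e-12, None)).sum())
    df = max(len(groups) * (n_cat - 1) - (n_cat - 1), 1)
    return {
        "chi2": chi2,
        "df": df,
        "p": float(stats.chi2.sf(chi2, df)),
        "n_strata": len(groups),
    }


def _limited_information_stat(model: PCMModel, matrix: ResponseMatrix):
    """First- and second-order margin discrepancy statistic and RMSEA.

    Compares observed univariate and bivariate category proportions
    (pairwise-complete) against their model-implied values under the
    calibration prior.  The full contingency table is far too sparse at
    typical sample sizes, so only these low-order margins are used.
    """
    order = [matrix.item_index(i) for i in model.item_ids]
    x = _encode(matrix)[:, order]
    n_items = len(model.bank)
    quad = model.quadrature
    probs = [category_probabilities(it.deltas, quad.nodes) for it in model.bank]  # (nodes, K)
    w = quad.weights
    chi2 = 0.0
    n_cells = 0
    for j in range(n_items):
        obs_mask = x[:, j] >= 0
        n_j = int(obs_mask.sum())
        if n_j == 0:
            continue
        n_cat = probs[j].shape[1]
        p_obs = np.bincount(x[obs_mask, j], minlength=n_cat) / n_j
        p_exp = w @ probs[j]
        chi2 += n_j * float(((p_obs - p_exp) ** 2 / np.clip(p_exp, 1e-12, None)).sum())
        n_cells += n_cat - 1
    for j in range(n_items):
        for l in range(j + 1, n_items):
            both = (x[:, j] >= 0) & (x[:, l] >= 0)
            n_jl = int(both.sum())
            if n_jl < 10:
                continue
            kj, kl = probs[j].shape[1], probs[l].shape[1]
            p_obs = np.zeros((kj, kl))
            np.add.at(p_obs, (x[both, j], x[both, l]), 1.0)
            p_obs /= n_jl
            p_exp = np.einsum("q,qa,qb->ab", w, probs[j], probs[l])
            chi2 += n_jl * float(((p_obs - p_exp) ** 2 / np.clip(p_exp, 1e-12, None)).sum())
            n_cells += (kj - 1) * (kl - 1)
    n_params = sum(len(it.deltas) for it in model.bank)
    df = max(n_cells - n_params, 1)
    n_eff = matrix.n_persons
    rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * n_eff)))
    # 90% CI via the noncentral chi-square inversion used for RMSEA
    def ncp_bound(q):
        lo, hi = 0.0, max(chi2 * 2, 10.0)
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if stats.ncx2.cdf(chi2, df, mid) > q:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)
    try:
        lam_hi = ncp_bound(0.05)
        lam_lo = ncp_bound(0.95)
        ci = (
            float(np.sqrt(max(lam_lo, 0.0) / (df * n_eff))),
            float(np.sqrt(max(lam_hi, 0.0) / (df * n_eff))),
        )
    except Exception:  # pragma: no cover - CI is advisory
        ci = (np.nan, np.nan)
    return chi2, df, rmsea, ci


def fit_statistics(model: PCMModel, matrix: ResponseMatrix, n_strata: int = 10) -> FitReport:
    """Item- and scale-level goodness of fit plus marginal reliability."""
    order = [matrix.item_index(i) for i in model.item_ids]
    x = _encode(matrix)[:, order]
    ll = _person_loglik_grid(model, x)
    item_fit = {}
    for j, it in enumerate(model.bank):
        item_fit[it.item_id] = _item_fit_chi2(model, x, ll, j, n_strata)
    chi2, df, rmsea, ci = _limited_information_stat(model, matrix)
    rel = marginal_reliability(model.bank, model.prior_mean, model.prior_sd)
    return FitReport(
        model_chi2=chi2,
        model_df=df,
        model_p=float(stats.chi2.sf(chi2, df)),
        rmsea=rmsea,
        rmsea_ci=ci,
        item_fit=item_fit,
        marginal_reliability=rel,
        merge_log=list(model.merge_log),
    )


# ---------------------------------------------------------------------------
# IRT-based imputation
# ---------------------------------------------------------------------------

def impute_missing(
    model: PCMModel,
    matrix: ResponseMatrix,
    method: str = "modal",
    rng: np.random.Generator | None = None,
) -> ResponseMatrix:
    """Fill missing cells from the model at each person's EAP theta.

    ``modal`` (default, deterministic) inserts the most probable category;
    ``sample`` draws from the category distribution (requires ``rng``).
    Persons with no observed responses are imputed at the prior mean.
    """
    if method not in ("modal", "sample"):
        raise ValueError("method must be 'modal' or 'sample'")
    if method == "sample" and rng is None:
        raise ValueError("sampled imputation needs an rng for reproducibility")
    theta, _ = _eap_arrays(model, matrix)
    out = matrix.copy()
    resp = out.responses
    col_of = {iid: matrix.item_index(iid) for iid in model.item_ids}
    for it in model.bank:
        j = col_of[it.item_id]
        miss = np.isnan(resp[:, j])
        if not miss.any():
            continue
        p = category_probabilities(it.deltas, theta[miss])
        if method == "modal":
            fill = p.argmax(axis=1)
        else:
            u = rng.random(p.shape[0])[:, None]
            fill = (u > p.cumsum(axis=1)).sum(axis=1)
        resp[miss, j] = fill
    return ResponseMatrix(resp, out.person_ids, out.item_ids, out.max_cat, out.group)
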