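"""Synthetic response data with the statistical structure the pipeline assumes.

The generator draws latent traits from a Gaussian, produces polytomous
responses from the partial credit model, and can inject the pathologies the
purification pipeline is designed to catch:

* ``disordered_thresholds`` — the item's generating thresholds are reversed
  (non-ascending), so some category is never the modal response;
* ``low_scalability`` — the item is generated with a discrimination below 1
  (generalized-PCM draw), weakening its relation to the common trait;
* ``nonmonotone`` — persons in a mid-range theta band respond at a lowered
  effective theta, so the item's step curves dip and recover; the shift is
  solved numerically so the maximum drop in a step probability equals the
  requested magnitude;
* ``reversed`` — the item is generated at the mirrored trait (a gross
  monotonicity violation detectable even at modest sample sizes);
* ``dif`` — one group's generating thresholds are shifted (uniform DIF);
* ``local_dependency`` — a partner item's response is overwritten with a
  mixture copy of its pair (applied post hoc to a generated matrix).

Defaults emulate the development study: 67 five-category items, 267
respondents, theta ~ Normal(-0.08, SD 1.90), 16% responses missing completely
at random, a retest subsample of 67 with latent correlation 0.75, and a
service-user / carer / both / unreported group mix of 66/15/12/7 percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .data_io import Item, ItemBank, ResponseMatrix
from .pcm import category_probabilities

__all__ = [
    "Pathology",
    "RetestDesign",
    "SimulationDesign",
    "simulate_responses",
    "simulate_retest",
    "inject_local_dependency",
    "inject_dif",
    "default_study_design",
    "study_pathologies",
    "random_bank",
]

PATHOLOGY_KINDS = (
    "disordered_thresholds",
    "local_dependency",
    "dif",
    "low_scalability",
    "nonmonotone",
    "reversed",
)

#: Study-emulation group mix (service users / carers / both / not reported).
DEFAULT_GROUP_PROBS = {"service_user": 0.66, "carer": 0.15, "both": 0.12, "unreported": 0.07}


@dataclass(frozen=True)
class Pathology:
    kind: str
    item_ids: tuple[str, ...]
    magnitude: float
    #: for ``dif``: the group whose thresholds are shifted
    group: str = "carer"

    def __post_init__(self) -> None:
        if self.kind not in PATHOLOGY_KINDS:
            raise ValueError(f"unknown pathology kind {self.kind!r}")
        object.__setattr__(self, "item_ids", tuple(str(i) for i in self.item_ids))


@dataclass(frozen=True)
class RetestDesign:
    n_retest: int
    theta_correlation: float

    def __post_init__(self) -> None:
        if not 0 < self.theta_correlation <= 1:
            raise ValueError("theta_correlation must be in (0, 1]")


@dataclass
class SimulationDesign:
    bank: ItemBank
    n_persons: int
    theta_mean: float = -0.08
    theta_sd: float = 1.90
    missing_rate: float = 0.16
    group_probs: dict[str, float] | None = None
    retest: RetestDesign | None = None
    pathologies: list[Pathology] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.theta_sd <= 0:
            raise ValueError("theta_sd must be positive")
        bank_ids = set(self.bank.item_ids)
        for p in self.pathologies:
            if p.kind == "local_dependency":
                continue  # applied post hoc, validated there
            missing = set(p.item_ids) - bank_ids
            if missing:
                raise ValueError(f"pathology items {sorted(missing)} not in bank")
        if self.retest and self.retest.n_retest > self.n_persons:
            raise ValueError("n_retest exceeds n_persons")


def random_bank(
    n_items: int,
    n_categories: int = 5,
    delta_range: tuple[float, float] = (-2.5, 2.5),
    seed: int = 0,
    prefix: str = "item",
) -> ItemBank:
    """Bank of items with thresholds drawn uniformly then sorted (ordered)."""
    rng = np.random.default_rng(seed)
    items = []
    for j in range(n_items):
        deltas = np.sort(rng.uniform(*delta_range, size=n_categories - 1))
        items.append(Item(f"{prefix}{j + 1}", "", tuple(deltas), tuple(range(n_categories))))
    return ItemBank(items)


# ---------------------------------------------------------------------------
# Pathology helpers
# ---------------------------------------------------------------------------

def _disorder(deltas: np.ndarray) -> np.ndarray:
    """Reverse the thresholds so they are non-ascending."""
    return np.sort(deltas)[::-1].copy()


def _dip_shift(deltas: np.ndarray, magnitude: float, anchor: float) -> float:
    """Theta shift that lowers some step curve by ``magnitude`` relative to
    its level at ``anchor``; solved numerically from the model curves.  If no
    shift can produce a drop that deep, the largest achievable shift is used."""

    def max_drop(s: float) -> float:
        p0 = category_probabilities(deltas, np.array([anchor]))[0]
        p1 = category_probabilities(deltas, np.array([anchor - s]))[0]
        steps0 = 1.0 - np.cumsum(p0)[:-1]
        steps1 = 1.0 - np.cumsum(p1)[:-1]
        return float(np.max(steps0 - steps1))

    try:
        return float(optimize.brentq(lambda s: max_drop(s) - magnitude, 1e-6, 30.0))
    except ValueError:
        return 30.0  # magnitude unattainable at this edge; use the max drop


def _pathology_lookup(design: SimulationDesign) -> dict[str, list[Pathology]]:
    table: dict[str, list[Pathology]] = {}
    for p in design.pathologies:
        if p.kind == "local_dependency":
            continue
        for iid in p.item_ids:
            table.setdefault(iid, []).append(p)
    return table


def _gpcm_probabilities(deltas: np.ndarray, theta: np.ndarray, slope: float) -> np.ndarray:
    """Generalized PCM category probabilities (slope < 1 = weak item)."""
    n_cat = deltas.size + 1
    cum_delta = np.concatenate([[0.0], np.cumsum(deltas)])
    s = slope * (theta[..., None] * np.arange(n_cat) - cum_delta)
    s -= s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


def _draw(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(p.shape[:-1])[..., None]
    return (u > np.cumsum(p, axis=-1)).sum(axis=-1)


# ---------------------------------------------------------------------------
# Main generators
# ---------------------------------------------------------------------------

def _generate_responses(
    design: SimulationDesign,
    theta: np.ndarray,
    groups: np.ndarray | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Raw category codes (float) for each person x item, before missingness."""
    n = theta.size
    pathologies = _pathology_lookup(design)
    out = np.empty((n, len(design.bank)))
    for j, item in enumerate(design.bank):
        deltas = np.asarray(item.deltas, dtype=float)
        slope = 1.0
        dip = 0.0
        reverse = False
        dif_shift = np.zeros(n)
        for p in pathologies.get(item.item_id, []):
            if p.kind == "disordered_thresholds":
                deltas = _disorder(deltas)
            elif p.kind == "low_scalability":
                slope = p.magnitude
            elif p.kind == "nonmonotone":
                # anchor the dip to the curve level just below the band so the
                # drop stays observable after rest-score grouping smears theta
                anchor = design.theta_mean - 0.8 * design.theta_sd
                dip = _dip_shift(deltas, p.magnitude, anchor)
            elif p.kind == "reversed":
                reverse = True
            elif p.kind == "dif":
                if groups is None:
                    raise ValueError("dif pathology requires group labels")
                dif_shift = np.where(groups == p.group, p.magnitude, 0.0)
        t_eff = theta.copy()
        if reverse:
            # gross monotonicity violation: the item runs against the trait
            t_eff = 2 * design.theta_mean - t_eff
        if dip:
            # persons in a mid-range theta band all respond at one depressed
            # effective trait level, set so a step probability sits
            # ~magnitude below its level just under the band; the curve dips
            # across the band and recovers above it
            half_w = 0.4 * design.theta_sd
            anchor = design.theta_mean - 0.8 * design.theta_sd
            band = np.abs(theta - design.theta_mean) < half_w
            t_eff = np.where(band, anchor - dip, t_eff)
        t_eff = t_eff - dif_shift
        if slope == 1.0:
            p_cat = category_probabilities(deltas, t_eff)
        else:
            p_cat = _gpcm_probabilities(deltas, t_eff, slope)
        out[:, j] = _draw(p_cat, rng)
    return out


def _draw_groups(design: SimulationDesign) -> np.ndarray | None:
    """Per-person group labels from a dedicated stream, so the baseline and
    retest occasions see the same assignment."""
    if not design.group_probs:
        return None
    rng = np.random.default_rng([design.seed, 1])
    labels = list(design.group_probs)
    probs = np.array([design.group_probs[g] for g in labels], dtype=float)
    return rng.choice(labels, size=design.n_persons, p=probs / probs.sum()).astype(object)


def simulate_responses(design: SimulationDesign) -> tuple[ResponseMatrix, np.ndarray]:
    """Generate a baseline response matrix; returns (matrix, true thetas).

    Responses come from the PCM (or its pathological variants) at each
    person's theta; missingness is applied completely at random at
    ``design.missing_rate``.  Fully reproducible from ``design.seed``.
    """
    rng = np.random.default_rng([design.seed, 0])
    theta = rng.normal(design.theta_mean, design.theta_sd, design.n_persons)
    groups = _draw_groups(design)
    resp = _generate_responses(design, theta, groups, rng)
    if design.missing_rate > 0:
        miss = rng.random(resp.shape) < design.missing_rate
        resp[miss] = np.nan
    matrix = ResponseMatrix(
        resp,
        [f"p{i + 1}" for i in range(design.n_persons)],
        design.bank.item_ids,
        np.array([len(it.deltas) for it in design.bank]),  # generation is on the scored metric
        groups,
    )
    # apply post-hoc local-dependency pathologies
    for p in design.pathologies:
        if p.kind != "local_dependency":
            continue
        if len(p.item_ids) != 2:
            raise ValueError("local_dependency pathology needs an item pair")
        matrix = inject_local_dependency(matrix, p.item_ids, p.magnitude, rng)
    return matrix, theta


def simulate_retest(design: SimulationDesign, baseline_theta: np.ndarray) -> tuple[ResponseMatrix, np.ndarray]:
    """Two-week retest responses for the first ``n_retest`` baseline persons.

    Retest traits regress toward the population mean:
    ``theta_2 = rho * (theta_1 - mu) + mu + sqrt(1 - rho^2) * sigma * z``.
    Person ids match the baseline so occasions can be paired.
    """
    if design.retest is None:
        raise ValueError("design has no retest block")
    rng = np.random.default_rng([design.seed, 2])
    rho = design.retest.theta_correlation
    n = design.retest.n_retest
    idx = np.arange(n)
    mu, sd = design.theta_mean, design.theta_sd
    z = rng.normal(size=n)
    theta2 = rho * (baseline_theta[idx] - mu) + mu + np.sqrt(1 - rho**2) * sd * z
    groups = _draw_groups(design)
    groups = groups[idx] if groups is not None else None
    retest_design = replace(design, n_persons=n)
    resp = _generate_responses(retest_design, theta2, groups, rng)
    if design.missing_rate > 0:
        miss = rng.random(resp.shape) < design.missing_rate
        resp[miss] = np.nan
    matrix = ResponseMatrix(
        resp,
        [f"p{i + 1}" for i in idx],
        design.bank.item_ids,
        np.array([len(it.deltas) for it in design.bank]),
        None,
    )
    return matrix, theta2


def inject_local_dependency(
    matrix: ResponseMatrix,
    item_pair: Sequence[str],
    strength: float,
    rng: np.random.Generator | None = None,
) -> ResponseMatrix:
    """Make the second item of a pair a probabilistic copy of the first.

    Wherever both responses are observed, the second item's response is
    replaced by the first item's with probability ``strength`` and otherwise
    kept as its original model draw.
    """
    if not 0 <= strength <= 1:
        raise ValueError("strength must be in [0, 1]")
    rng = rng or np.random.default_rng(0)
    a, b = (matrix.item_index(i) for i in item_pair)
    out = matrix.copy()
    resp = out.responses
    both = ~np.isnan(resp[:, a]) & ~np.isnan(resp[:, b])
    copy_mask = both & (rng.random(matrix.n_persons) < strength)
    cap = out.max_cat[b]
    resp[copy_mask, b] = np.minimum(resp[copy_mask, a], cap)
    return ResponseMatrix(resp, out.person_ids, out.item_ids, out.max_cat, out.group)


def inject_dif(design: SimulationDesign, item_id: str, group_shift: float, group: str = "carer") -> SimulationDesign:
    """Return a design whose generating thresholds for ``item_id`` are offset
    by ``group_shift`` for one group (uniform DIF)."""
    if item_id not in design.bank.item_ids:
        raise ValueError(f"item {item_id!r} not in bank")
    if not design.group_probs:
        raise ValueError("design has no group labels; set group_probs first")
    p = Pathology("dif", (item_id,), group_shift, group=group)
    return replace(design, pathologies=[*design.pathologies, p])


# ---------------------------------------------------------------------------
# Study emulation
# ---------------------------------------------------------------------------

def default_study_design(seed: int = 0, pathologies: list[Pathology] | None = None) -> SimulationDesign:
    """The development-study emulation: 67 five-category items, 267 persons,
    theta ~ Normal(-0.08, 1.90), 16% MCAR missingness, retest n=67 with
    latent correlation 0.75, and the observed respondent-group mix."""
    bank = random_bank(67, 5, seed=seed)
    return SimulationDesign(
        bank=bank,
        n_persons=267,
        theta_mean=-0.08,
        theta_sd=1.90,
        missing_rate=0.16,
        group_probs=dict(DEFAULT_GROUP_PROBS),
        retest=RetestDesign(67, 0.75),
        pathologies=list(pathologies or []),
        seed=seed,
    )


def study_pathologies(bank: ItemBank) -> list[Pathology]:
    """Injected pathology set for end-to-end pipeline checks: disordered
    thresholds, two weak (low-scalability) items, two non-monotone items,
    one locally dependent pair, and one uniform-DIF item."""
    ids = bank.item_ids
    return [
        Pathology("disordered_thresholds", (ids[0], ids[1]), 1.0),
        # slope 0.10 pushes item H below the 0.30 keep rule at study-scale n
        # (healthy unit-slope items sit near H ~ .7 at this trait spread)
        Pathology("low_scalability", (ids[2], ids[3]), 0.10),
        # reversed items are gross monotonicity violations, detectable at
        # study-scale n; the subtler mid-range dip is exercised separately
        Pathology("reversed", (ids[4], ids[5]), 1.0),
        Pathology("local_dependency", (ids[6], ids[7]), 0.8),
        # a 1.5-logit shift reproduces the meaningful-DIF effect size
        # (McFadden R2 change ~ .06) seen in real scale-development data
        Pathology("dif", (ids[8],), 1.5),
    ]
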