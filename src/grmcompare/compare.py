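"""The three group-mean-comparison approaches.

Sum-score + Welch test, IRT-model likelihood-ratio test, and IRT-EAP +
Welch test, each wrapped into a :class:`MethodResult` with decision,
p-value, and standardized effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import t as _t

from .model import (
    FitResult,
    ItemParameters,
    LatentGrid,
    eap_scores,
    fit_grm_multigroup,
    likelihood_ratio_test,
)
from .simulate import SimulatedDataset

ALPHA = 0.05

#: Calibration-error half-width for the pre-calibrated item parameters
#: consumed by the EAP approach.
JIGGLE_RADIUS = 0.2


@dataclass
class MethodResult:
    """One approach's outcome for one replication."""

    method: str  # sum_score | irt_model | irt_eap
    prescreened: bool
    reject: bool
    p_value: float
    effect_size: float
    diagnostics: dict = field(default_factory=dict)


class DegenerateGroupError(ValueError):
    """A group retained fewer than two scored cases."""


def sum_scores(
    responses: np.ndarray, item_subset: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Listwise-deleted sum scores over an item subset.

    Returns (scores for included persons, boolean inclusion mask).
    Persons with any missing response on the subset are excluded.
    """
    item_subset = np.asarray(item_subset, dtype=int)
    if item_subset.size == 0:
        raise ValueError("item subset must be non-empty")
    sub = np.asarray(responses, dtype=int)[:, item_subset]
    included = np.all(sub >= 0, axis=1)
    return sub[included].sum(axis=1), included


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch's t-test; returns (statistic, p).

    Conventions: both groups constant with equal means -> (0, 1); both
    constant with unequal means -> (+-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateGroupError("each group needs at least two scores")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if vx == 0 and vy == 0:
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    se2 = vx / len(x) + vy / len(y)
    stat = diff / np.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    return float(stat), float(2.0 * _t.sf(abs(stat), df))


def pooled_effect_size(
    mean_focal: float,
    sd_focal: float,
    n_focal: int,
    mean_ref: float,
    sd_ref: float,
    n_ref: int,
) -> float:
    """(focal mean - reference mean) / (n-1)-weighted pooled SD."""
    if not (sd_focal > 0 or sd_ref > 0):
        raise ValueError("at least one group must have positive SD")
    pooled = np.sqrt(
        ((n_focal - 1) * sd_focal**2 + (n_ref - 1) * sd_ref**2)
        / (n_focal + n_ref - 2)
    )
    return float((mean_focal - mean_ref) / pooled)


def jiggle_items(
    items: Sequence[ItemParameters],
    rng: np.random.Generator,
    radius: float = JIGGLE_RADIUS,
    max_tries: int = 1000,
) -> list[ItemParameters]:
    """Perturb every parameter by i.i.d. U(-radius, radius).

    Emulates pre-calibration error.  If an item's jiggled thresholds lose
    their ordering (or its slope its sign), that item's jiggle is
    redrawn.
    """
    out = []
    for it in items:
        for _ in range(max_tries):
            a = it.discrimination + rng.uniform(-radius, radius)
            b = it.thresholds + rng.uniform(-radius, radius, size=len(it.thresholds))
            if a > 0 and np.all(np.diff(b) > 0):
                out.append(ItemParameters(it.n_categories, a, b))
                break
        else:  # pragma: no cover - requires pathological parameters
            raise RuntimeError("could not draw a valid jiggle")
    return out


def _score_test(
    scores_focal: np.ndarray, scores_ref: np.ndarray
) -> tuple[bool, float, float]:
    stat, p = welch_t_test(scores_focal, scores_ref)
    effect = pooled_effect_size(
        scores_focal.mean(),
        scores_focal.std(ddof=1),
        len(scores_focal),
        scores_ref.mean(),
        scores_ref.std(ddof=1),
        len(scores_ref),
    )
    return bool(p < ALPHA), p, effect


def run_sum_score(
    dataset: SimulatedDataset,
    item_subset: Sequence[int],
    prescreened: bool = False,
) -> MethodResult:
    """Sum-score approach: listwise deletion, Welch test, pooled d."""
    try:
        s_ref, inc_ref = sum_scores(dataset.resp_ref, item_subset)
        s_foc, inc_foc = sum_scores(dataset.resp_focal, item_subset)
        reject, p, effect = _score_test(s_foc, s_ref)
        diag = {
            "n_excluded_ref": int((~inc_ref).sum()),
            "n_excluded_focal": int((~inc_foc).sum()),
        }
    except (DegenerateGroupError, ValueError) as exc:
        return MethodResult(
            "sum_score", prescreened, False, np.nan, np.nan, {"error": str(exc)}
        )
    return MethodResult("sum_score", prescreened, reject, p, effect, diag)


def run_irt_model(
    dataset: SimulatedDataset,
    constraint_plan: np.ndarray | None = None,
    prescreened: bool = False,
    grid: LatentGrid | None = None,
    start: FitResult | None = None,
) -> MethodResult:
    """IRT-model approach: LRT on the equal-means constraint (df = 1).

    The general fit frees the focal mean and variance; the restricted fit
    pins the focal mean at zero.  The effect size is the estimated focal
    mean over the size-weighted pooled latent SD (reference SD fixed at
    one).
    """
    general = fit_grm_multigroup(
        dataset.resp_ref,
        dataset.resp_focal,
        invariant=constraint_plan,
        mean_constraint=False,
        grid=grid,
        start=start,
    )
    restricted = fit_grm_multigroup(
        dataset.resp_ref,
        dataset.resp_focal,
        invariant=constraint_plan,
        mean_constraint=True,
        grid=grid,
        start=general,
    )
    if restricted.log_likelihood > general.log_likelihood:
        # flat-likelihood stall in the general fit: restart it from the
        # restricted solution, which is feasible under the general model
        general = fit_grm_multigroup(
            dataset.resp_ref,
            dataset.resp_focal,
            invariant=constraint_plan,
            mean_constraint=False,
            grid=grid,
            start=restricted,
        )
    stat, df, p = likelihood_ratio_test(general, restricted)
    mu = general.group_estimates.focal_mean
    var = general.group_estimates.focal_variance
    n_ref, n_foc = len(dataset.resp_ref), len(dataset.resp_focal)
    effect = pooled_effect_size(mu, np.sqrt(var), n_foc, 0.0, 1.0, n_ref)
    return MethodResult(
        "irt_model",
        prescreened,
        bool(p < ALPHA),
        p,
        effect,
        {
            "statistic": stat,
            "df": df,
            "converged_general": general.converged,
            "converged_restricted": restricted.converged,
        },
    )


def run_irt_eap(
    dataset: SimulatedDataset,
    calibrated_items: Sequence[ItemParameters],
    item_subset: Sequence[int],
    prescreened: bool = False,
    grid: LatentGrid | None = None,
) -> MethodResult:
    """IRT-EAP approach: EAP scores from pre-calibrated reference
    parameters, then the same Welch test and pooled effect size.

    Missing responses are simply omitted from each posterior, so no case
    is dropped; an all-missing person contributes the prior mean.
    """
    item_subset = sorted(int(j) for j in item_subset)
    if len(item_subset) == 0:
        raise ValueError("item subset must be non-empty")
    items = [calibrated_items[j] for j in item_subset]
    eap_ref, _ = eap_scores(dataset.resp_ref[:, item_subset], items, grid)
    eap_foc, _ = eap_scores(dataset.resp_focal[:, item_subset], items, grid)
    try:
        reject, p, effect = _score_test(eap_foc, eap_ref)
    except (DegenerateGroupError, ValueError) as exc:
        return MethodResult(
            "irt_eap", prescreened, False, np.nan, np.nan, {"error": str(exc)}
        )
    return MethodResult("irt_eap", prescreened, reject, p, effect, {})
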