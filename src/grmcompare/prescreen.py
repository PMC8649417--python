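"""IRT-LRT DIF prescreening.

All-others-as-anchors scan, rank-based anchor selection, and anchored
retesting.  Produces the clean-item set used by the sum-score and EAP
approaches and the constraint plan used by the IRT-model approach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import FitResult, LatentGrid, fit_grm_multigroup, likelihood_ratio_test
from .simulate import SimulatedDataset

ALPHA = 0.05

#: Fraction of items selected as anchors (nearest integer, floor one).
ANCHOR_FRACTION = 0.2


@dataclass
class DifScanItem:
    """One item's all-others-as-anchors LRT outcome."""

    item: int
    statistic: float
    df: int
    p_value: float
    discrimination: float  # constrained-fit slope estimate, used for ranking

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass
class PrescreenOutcome:
    """Partition of the item set produced by prescreening.

    ``clean_items`` = anchors plus retest-nonsignificant items;
    ``dif_items`` is the complement.  ``constraint_plan`` marks clean
    items group-invariant for the IRT-model approach.
    """

    anchors: list
    clean_items: list
    dif_items: list
    constraint_plan: np.ndarray
    scan: list = field(default_factory=list)
    retests: dict = field(default_factory=dict)


def anchor_count(n_items: int) -> int:
    return max(1, int(np.rint(ANCHOR_FRACTION * n_items)))


def aoaa_scan(
    dataset: SimulatedDataset, grid: LatentGrid | None = None
) -> tuple[list[DifScanItem], FitResult]:
    """Test every item for DIF with all other items as anchors.

    The baseline holds all items invariant with free focal moments; each
    item's test frees that item's parameters in both groups.  Returns the
    per-item results and the baseline fit (whose slope estimates feed the
    anchor ranking).
    """
    J = dataset.n_items
    base = fit_grm_multigroup(
        dataset.resp_ref, dataset.resp_focal, invariant=None, grid=grid
    )
    results = []
    for j in range(J):
        item_est = base.item_estimates["reference"][j]
        if item_est is None:  # excluded from the likelihood: untestable
            results.append(DifScanItem(j, 0.0, 0, 1.0, np.nan))
            continue
        plan = np.ones(J, dtype=bool)
        plan[j] = False
        free_fit = fit_grm_multigroup(
            dataset.resp_ref, dataset.resp_focal, invariant=plan, grid=grid,
            start=base,
        )
        stat, df, p = likelihood_ratio_test(free_fit, base)
        results.append(DifScanItem(j, stat, df, p, item_est.discrimination))
    return results, base


def select_anchors(scan: list[DifScanItem], k: int | None = None) -> list[int]:
    """Rank-based anchor selection.

    If at least ``k`` items are nonsignificant, take the ``k`` of them
    with the largest constrained-fit slopes; otherwise take the ``k``
    items with the smallest test statistics.  Ties break by item id.
    """
    if k is None:
        k = anchor_count(len(scan))
    if k < 1:
        raise ValueError("need at least one anchor")
    nonsig = [s for s in scan if not s.significant]
    if len(nonsig) >= k:
        ranked = sorted(nonsig, key=lambda s: (-s.discrimination, s.item))
    else:
        ranked = sorted(scan, key=lambda s: (s.statistic, s.item))
    return sorted(s.item for s in ranked[:k])


def retest_with_anchors(
    dataset: SimulatedDataset,
    anchors: list[int],
    grid: LatentGrid | None = None,
    start=None,
) -> dict[int, DifScanItem]:
    """Retest each non-anchor against the fixed anchor metric.

    Both compared models hold the anchors invariant and every other
    non-anchor group-specific; the tested item is invariant in the
    restricted model and free in the general one, so each retest isolates
    a single item.

    All item tests share one general (anchors-only) fit.  If any
    restricted fit ends up above the general fit (a flat-likelihood
    optimisation stall), the general model is refit from that restricted
    solution — a feasible start, so its likelihood can only improve — and
    every statistic is computed against the final general likelihood.
    """
    J = dataset.n_items
    anchors = sorted(int(a) for a in anchors)
    anchor_mask = np.zeros(J, dtype=bool)
    anchor_mask[anchors] = True
    general = fit_grm_multigroup(
        dataset.resp_ref, dataset.resp_focal, invariant=anchor_mask, grid=grid,
        start=start,
    )
    restricted_fits: dict[int, object] = {}
    for j in range(J):
        if anchor_mask[j]:
            continue
        if general.item_estimates["reference"][j] is None:
            continue
        plan = anchor_mask.copy()
        plan[j] = True
        restricted = fit_grm_multigroup(
            dataset.resp_ref, dataset.resp_focal, invariant=plan, grid=grid,
            start=general,
        )
        restricted_fits[j] = restricted
        if restricted.log_likelihood > general.log_likelihood:
            general = fit_grm_multigroup(
                dataset.resp_ref, dataset.resp_focal, invariant=anchor_mask,
                grid=grid, start=restricted,
            )
    out: dict[int, DifScanItem] = {}
    for j in range(J):
        if anchor_mask[j]:
            continue
        if j not in restricted_fits:
            out[j] = DifScanItem(j, 0.0, 0, 1.0, np.nan)
            continue
        restricted = restricted_fits[j]
        stat, df, p = likelihood_ratio_test(general, restricted)
        disc = restricted.item_estimates["reference"][j].discrimination
        out[j] = DifScanItem(j, stat, df, p, disc)
    return out


def prescreen(
    dataset: SimulatedDataset, grid: LatentGrid | None = None
) -> PrescreenOutcome:
    """Full prescreening pipeline: scan, anchor selection, retest."""
    scan, base = aoaa_scan(dataset, grid)
    anchors = select_anchors(scan)
    retests = retest_with_anchors(dataset, anchors, grid, start=base)
    clean = set(anchors) | {j for j, r in retests.items() if not r.significant}
    dif_items = sorted(set(range(dataset.n_items)) - clean)
    plan = np.zeros(dataset.n_items, dtype=bool)
    plan[sorted(clean)] = True
    return PrescreenOutcome(
        anchors=sorted(anchors),
        clean_items=sorted(clean),
        dif_items=dif_items,
        constraint_plan=plan,
        scan=scan,
        retests=retests,
    )
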