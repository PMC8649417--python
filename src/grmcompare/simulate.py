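"""Data-generating machinery for the simulation study.

Item banks, condition-specific item draws, true-score simulation,
directional DIF injection, graded-response data generation, MAR
missingness, and the standardized differential-test-functioning (DTF)
effect size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from scipy.special import expit

from .model import MISSING, ItemParameters

#: Uniform slope ranges per discrimination level (logistic metric).
A_RANGES = {"high": (1.7, 3.5), "low": (0.5, 1.0)}

#: Homogeneous-thresholds window around the benchmark item.
HOMOGENEITY_WINDOW = 0.25

#: Fractions fixed by the study design.
DIF_ITEM_FRACTION = 0.4
MISSING_ITEM_FRACTION = 0.2
MISSING_SUBJECT_FRACTION = 0.3

#: Declared factor levels of the condition grid (order is the canonical
#: declaration order used for grid construction and tree splits).
CONDITION_LEVELS = {
    "n_per_group": (100, 400),
    "n_items": (5, 20),
    "discrimination": ("high", "low"),
    "n_categories": (2, 5),
    "thresholds_mode": ("homogeneous", "diverse"),
    "dif": ("absent", "present"),
    "missing": ("absent", "present"),
    "true_focal_mean": (0.0, 0.5),
}


class ConditionInfeasibleError(RuntimeError):
    """Raised when repeated homogeneous-benchmark restarts are exhausted."""


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the crossed simulation design."""

    n_per_group: int
    n_items: int
    discrimination: str
    n_categories: int
    thresholds_mode: str
    dif: str
    missing: str
    true_focal_mean: float

    def __post_init__(self) -> None:
        for name, levels in CONDITION_LEVELS.items():
            if getattr(self, name) not in levels:
                raise ValueError(f"{name}={getattr(self, name)!r} not in {levels}")

    @property
    def item_type(self) -> str:
        return "dichotomous" if self.n_categories == 2 else "polytomous"

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in CONDITION_LEVELS}


def _truncated_normal(rng, mean, sd, lower, upper, size):
    """Rejection sampling from a truncated normal (wide regions only)."""
    out = np.empty(size)
    n = 0
    while n < size:
        draw = rng.normal(mean, sd, size=size - n)
        keep = draw[(draw >= lower) & (draw <= upper)]
        out[n : n + keep.size] = keep
        n += keep.size
    return out


@dataclass
class ItemBank:
    """A pre-generated table of item parameters.

    ``a`` has shape (size,), ``b`` shape (size, V - 1) with strictly
    increasing rows.
    """

    item_type: str
    discrimination_level: str
    a: np.ndarray
    b: np.ndarray

    @property
    def size(self) -> int:
        return len(self.a)

    @property
    def n_categories(self) -> int:
        return self.b.shape[1] + 1

    def item(self, i: int) -> ItemParameters:
        return ItemParameters(self.n_categories, self.a[i], self.b[i].copy())


def build_item_bank(
    item_type: str,
    discrimination_level: str,
    size: int = 10_000,
    rng: np.random.Generator | None = None,
) -> ItemBank:
    """Generate an item bank from the study's truncated distributions.

    Dichotomous thresholds: N(0.1, SD 1.3) truncated to [-2.5, 2.4].
    Polytomous: b1 ~ N(-1, SD 1) truncated to [-3.5, 0.5], then three
    increments ~ N(0.8, SD 0.2) truncated to [0.4, 1.2], so the largest
    threshold lies in [0.1, 4.1].  Slopes are uniform on the level's
    range.
    """
    rng = rng or np.random.default_rng()
    lo, hi = A_RANGES[discrimination_level]
    a = rng.uniform(lo, hi, size=size)
    if item_type == "dichotomous":
        b = _truncated_normal(rng, 0.1, 1.3, -2.5, 2.4, size)[:, None]
    elif item_type == "polytomous":
        b1 = _truncated_normal(rng, -1.0, 1.0, -3.5, 0.5, size)
        steps = np.stack(
            [_truncated_normal(rng, 0.8, 0.2, 0.4, 1.2, size) for _ in range(3)],
            axis=1,
        )
        b = b1[:, None] + np.concatenate(
            [np.zeros((size, 1)), np.cumsum(steps, axis=1)], axis=1
        )
    else:
        raise ValueError(f"unknown item type {item_type!r}")
    return ItemBank(item_type, discrimination_level, a, b)


def draw_items(
    bank: ItemBank,
    n_items: int,
    thresholds_mode: str,
    rng: np.random.Generator,
    max_restarts: int = 1000,
) -> tuple[list[ItemParameters], np.ndarray]:
    """Draw a replication's item set from the bank.

    Diverse mode is a simple random sample without replacement.
    Homogeneous mode draws a benchmark item and requires every other
    item's thresholds to lie within +-0.25 of the benchmark's
    (per threshold); an insufficient candidate pool triggers a benchmark
    redraw, up to ``max_restarts`` attempts.
    """
    if thresholds_mode == "diverse":
        idx = rng.choice(bank.size, size=n_items, replace=False)
    elif thresholds_mode == "homogeneous":
        for _ in range(max_restarts):
            bench = int(rng.integers(bank.size))
            close = np.all(
                np.abs(bank.b - bank.b[bench]) <= HOMOGENEITY_WINDOW, axis=1
            )
            close[bench] = False
            candidates = np.flatnonzero(close)
            if candidates.size >= n_items - 1:
                rest = rng.choice(candidates, size=n_items - 1, replace=False)
                idx = np.concatenate([[bench], rest])
                break
        else:
            raise ConditionInfeasibleError(
                f"no homogeneous item set of size {n_items} found in "
                f"{max_restarts} benchmark redraws"
            )
    else:
        raise ValueError(f"unknown thresholds mode {thresholds_mode!r}")
    return [bank.item(i) for i in idx], np.asarray(idx, dtype=int)


def draw_true_scores(n: int, mean: float, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. normal trait draws with SD 1."""
    return rng.normal(mean, 1.0, size=n)


def apply_dif(
    items: Sequence[ItemParameters], rng: np.random.Generator
) -> tuple[list[ItemParameters], np.ndarray, dict]:
    """Disadvantage the focal group on 40% of the items.

    Each flagged item's focal slope is lowered by U(0, 0.3) and all of
    its thresholds are raised by a single shared U(0.5, 0.7) draw.  The
    input list is left untouched.
    """
    J = len(items)
    n_flag = int(np.rint(DIF_ITEM_FRACTION * J))
    flags = np.zeros(J, dtype=bool)
    flags[rng.choice(J, size=n_flag, replace=False)] = True
    focal, a_shift, b_shift = [], np.zeros(J), np.zeros(J)
    for j, it in enumerate(items):
        if flags[j]:
            a_shift[j] = rng.uniform(0.0, 0.3)
            b_shift[j] = rng.uniform(0.5, 0.7)
            focal.append(
                ItemParameters(
                    it.n_categories,
                    it.discrimination - a_shift[j],
                    it.thresholds + b_shift[j],
                )
            )
        else:
            focal.append(it.copy())
    return focal, flags, {"a_shift": a_shift, "b_shift": b_shift}


def simulate_responses(
    traits: np.ndarray, items: Sequence[ItemParameters], rng: np.random.Generator
) -> np.ndarray:
    """Draw a response matrix from the graded response model.

    One uniform per cell compared against the decreasing cumulative
    curves yields a categorical draw with the model's probabilities.
    """
    traits = np.asarray(traits, dtype=float)
    N, J = len(traits), len(items)
    out = np.empty((N, J), dtype=int)
    r = rng.random((N, J))
    for j, it in enumerate(items):
        C = expit(it.discrimination * (traits[:, None] - it.thresholds[None, :]))
        out[:, j] = (r[:, j][:, None] < C).sum(axis=1)
    return out


def impose_mar_missingness(
    responses: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Delete 20% of items' responses for 30% of subjects, MAR.

    Missingness-eligible items are drawn at random; subjects are sampled
    without replacement with probability increasing (logistically) in
    their standardized mean response on the non-eligible items, so the
    mechanism depends only on responses that remain observed.
    Returns (responses with missing cells, boolean deletion mask).
    """
    responses = np.asarray(responses, dtype=int)
    N, J = responses.shape
    n_items = int(np.rint(MISSING_ITEM_FRACTION * J))
    n_subj = int(np.rint(MISSING_SUBJECT_FRACTION * N))
    eligible = rng.choice(J, size=n_items, replace=False)
    keep = np.setdiff1d(np.arange(J), eligible)
    m = responses[:, keep].mean(axis=1)
    s = m.std()
    z = (m - m.mean()) / (s if s > 0 else 1.0)
    p = expit(z)
    selected = rng.choice(N, size=n_subj, replace=False, p=p / p.sum())
    out = responses.copy()
    mask = np.zeros((N, J), dtype=bool)
    out[np.ix_(selected, eligible)] = MISSING
    mask[np.ix_(selected, eligible)] = True
    return out, mask


def expected_test_score(
    items: Sequence[ItemParameters], traits: np.ndarray
) -> np.ndarray:
    """Model-expected sum score at each trait value.

    For a graded item the expected score is the sum of its cumulative
    category curves.
    """
    traits = np.asarray(traits, dtype=float)
    total = np.zeros(len(traits))
    for it in items:
        total += expit(
            it.discrimination * (traits[:, None] - it.thresholds[None, :])
        ).sum(axis=1)
    return total


@dataclass
class DTFResult:
    """Standardized expected-test-score difference on the focal sample."""

    effect_size: float


def dtf_effect_size(
    items_ref: Sequence[ItemParameters],
    items_focal: Sequence[ItemParameters],
    focal_traits: np.ndarray,
) -> DTFResult:
    """Signed DTF effect size.

    Difference between focal- and reference-parameter expected test
    scores averaged over the focal sample, standardized by the SD of the
    reference-parameter expected test scores in that same sample.
    """
    if len(items_ref) != len(items_focal):
        raise ValueError("item lists must be aligned")
    t_ref = expected_test_score(items_ref, focal_traits)
    t_foc = expected_test_score(items_focal, focal_traits)
    return DTFResult(float((t_foc - t_ref).mean() / t_ref.std(ddof=1)))


@dataclass
class SimulatedDataset:
    """One replication's generated data plus its generating truth."""

    condition: ConditionSpec
    resp_ref: np.ndarray
    resp_focal: np.ndarray
    theta_ref: np.ndarray
    theta_focal: np.ndarray
    items_ref: list
    items_focal: list
    dif_flags: np.ndarray
    missing_mask: np.ndarray  # pooled (2N, J), reference rows first
    item_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    provenance: dict = field(default_factory=dict)

    @property
    def n_items(self) -> int:
        return self.resp_ref.shape[1]


def generate_dataset(
    condition: ConditionSpec,
    banks: dict,
    rng: np.random.Generator,
) -> SimulatedDataset:
    """Generate one replication's dataset for a design cell.

    ``banks`` maps (item_type, discrimination_level) to an
    :class:`ItemBank`.
    """
    bank = banks[(condition.item_type, condition.discrimination)]
    items, idx = draw_items(bank, condition.n_items, condition.thresholds_mode, rng)
    theta_ref = draw_true_scores(condition.n_per_group, 0.0, rng)
    theta_foc = draw_true_scores(condition.n_per_group, condition.true_focal_mean, rng)
    if condition.dif == "present":
        items_focal, flags, dif_draws = apply_dif(items, rng)
    else:
        items_focal = [it.copy() for it in items]
        flags = np.zeros(condition.n_items, dtype=bool)
        dif_draws = {}
    resp_ref = simulate_responses(theta_ref, items, rng)
    resp_foc = simulate_responses(theta_foc, items_focal, rng)
    n = condition.n_per_group
    if condition.missing == "present":
        pooled, mask = impose_mar_missingness(np.vstack([resp_ref, resp_foc]), rng)
        resp_ref, resp_foc = pooled[:n], pooled[n:]
    else:
        mask = np.zeros((2 * n, condition.n_items), dtype=bool)
    return SimulatedDataset(
        condition=condition,
        resp_ref=resp_ref,
        resp_focal=resp_foc,
        theta_ref=theta_ref,
        theta_focal=theta_foc,
        items_ref=items,
        items_focal=items_focal,
        dif_flags=flags,
        missing_mask=mask,
        item_ids=idx,
        provenance={"dif_draws": {k: v.tolist() for k, v in dif_draws.items()}},
    )


def build_condition_grid() -> list[ConditionSpec]:
    """The full crossed design: 2^7 data features x 2 true means = 256."""
    names = list(CONDITION_LEVELS)
    return [
        ConditionSpec(**dict(zip(names, combo)))
        for combo in product(*CONDITION_LEVELS.values())
    ]
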