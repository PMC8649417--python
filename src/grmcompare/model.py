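"""Graded response model core.

Category probabilities, marginal maximum-likelihood estimation of a
two-group graded response model under configurable between-group
invariance constraints, likelihood-ratio testing of nested fits, and
expected-a-posteriori (EAP) trait scoring.

All slopes live on the pure logistic metric.  The classical 1.7 scaling
constant is used only by :func:`loading_from_discrimination`, never in
probability evaluation or estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm

#: Sentinel for a missing response in integer response matrices.
MISSING = -1

#: Logistic-to-normal-ogive scaling constant (conversion utility only).
LOGISTIC_SCALE_D = 1.7

# Box constraints for the unconstrained optimisation parameterisation.
# They are generous: they only rule out numerically degenerate fits.
_BOUND_LOG_A = (-4.6, 3.0)
_BOUND_B1 = (-10.0, 10.0)
_BOUND_LOG_D = (-4.6, 3.0)
_BOUND_MU = (-4.0, 4.0)
_BOUND_LOG_SD = (np.log(0.1), np.log(10.0))

_MIN_PROB = 1e-300


def _row_logsumexp(A: np.ndarray) -> np.ndarray:
    """Row-wise logsumexp without scipy's dispatch overhead."""
    m = A.max(axis=1)
    return m + np.log(np.exp(A - m[:, None]).sum(axis=1))


def _normalized_log_weights(nodes: np.ndarray, mean: float, sd: float) -> np.ndarray:
    lw = -0.5 * ((nodes - mean) / sd) ** 2
    m = lw.max()
    return lw - (m + np.log(np.exp(lw - m).sum()))


def loading_from_discrimination(a: float) -> float:
    """Standardized factor loading implied by a logistic-metric slope."""
    a_no = np.asarray(a, dtype=float) / LOGISTIC_SCALE_D
    return a_no / np.sqrt(1.0 + a_no**2)


@dataclass
class ItemParameters:
    """One item's graded-response parameters.

    Parameters
    ----------
    n_categories : int
        Number of ordered response categories ``V`` (>= 2).
    discrimination : float
        Positive slope on the logistic metric.
    thresholds : array-like of shape (V - 1,)
        Strictly increasing category thresholds.
    """

    n_categories: int
    discrimination: float
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.atleast_1d(np.asarray(self.thresholds, dtype=float))
        self.n_categories = int(self.n_categories)
        self.discrimination = float(self.discrimination)
        if self.n_categories < 2:
            raise ValueError("need at least two response categories")
        if self.thresholds.shape != (self.n_categories - 1,):
            raise ValueError(
                f"expected {self.n_categories - 1} thresholds, "
                f"got {self.thresholds.shape}"
            )
        if not self.discrimination > 0:
            raise ValueError("discrimination must be positive")
        if self.n_categories > 2 and np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    def copy(self) -> "ItemParameters":
        return ItemParameters(
            self.n_categories, self.discrimination, self.thresholds.copy()
        )


@dataclass
class LatentGrid:
    """Equally spaced quadrature grid for the latent trait.

    ``weights`` are standard-normal prior weights renormalised to sum to
    one; group-specific weights come from :meth:`log_weights`.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("grid nodes must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("grid weights must be non-negative")

    @classmethod
    def default(cls, n_nodes: int = 61, bound: float = 6.0) -> "LatentGrid":
        nodes = np.linspace(-bound, bound, n_nodes)
        lw = -0.5 * nodes**2
        w = np.exp(lw - logsumexp(lw))
        return cls(nodes, w)

    def log_weights(self, mean: float = 0.0, sd: float = 1.0) -> np.ndarray:
        """Renormalised log prior weights for a N(mean, sd^2) trait."""
        if not sd > 0:
            raise ValueError("sd must be positive")
        return _normalized_log_weights(self.nodes, mean, sd)


@dataclass
class GroupStructure:
    """Focal-group latent moments; the reference group is fixed N(0, 1)."""

    focal_mean: float = 0.0
    focal_variance: float = 1.0

    REFERENCE_MEAN = 0.0
    REFERENCE_VARIANCE = 1.0

    def __post_init__(self) -> None:
        if not self.focal_variance > 0:
            raise ValueError("focal variance must be positive")


def cumulative_prob(item: ItemParameters, theta: float, v: int) -> float:
    """P(response >= v | theta) for category index ``1 <= v <= V - 1``."""
    if not 1 <= v <= item.n_categories - 1:
        raise ValueError(
            f"category index {v} out of range 1..{item.n_categories - 1}"
        )
    return float(expit(item.discrimination * (theta - item.thresholds[v - 1])))


def _prob_table(a: float, b: np.ndarray, nodes: np.ndarray):
    """Category probabilities at every node: returns (P, C).

    P has shape (Q, V); C holds the V-1 cumulative curves.
    """
    C = expit(a * (nodes[:, None] - b[None, :]))
    Q, vm1 = C.shape
    P = np.empty((Q, vm1 + 1))
    P[:, 0] = 1.0 - C[:, 0]
    P[:, -1] = C[:, -1]
    if vm1 > 1:
        P[:, 1:-1] = C[:, :-1] - C[:, 1:]
    return np.clip(P, _MIN_PROB, 1.0), C


def category_prob(item: ItemParameters, theta: float) -> np.ndarray:
    """Probability vector over all V categories at ``theta``."""
    P, _ = _prob_table(
        item.discrimination, item.thresholds, np.atleast_1d(float(theta))
    )
    return P[0]


def pattern_loglik(
    pattern: Sequence[int], items: Sequence[ItemParameters], theta: float
) -> float:
    """Log-likelihood of one response pattern at a fixed trait value.

    Missing entries (negative values) are skipped; an all-missing pattern
    contributes ``0.0`` (an empty product).
    """
    pattern = np.asarray(pattern, dtype=int)
    if pattern.shape != (len(items),):
        raise ValueError("pattern length must equal the number of items")
    total = 0.0
    for u, item in zip(pattern, items):
        if u < 0:
            continue
        if u >= item.n_categories:
            raise ValueError(
                f"response {u} out of range for a {item.n_categories}-category item"
            )
        total += float(np.log(category_prob(item, theta)[u]))
    return total


def _loglik_matrix(resp: np.ndarray, log_tables: Sequence, Q: int) -> np.ndarray:
    """Per-person log pattern likelihood at each grid node, shape (N, Q)."""
    N = resp.shape[0]
    LL = np.zeros((N, Q))
    for j, logP in enumerate(log_tables):
        if logP is None:
            continue
        u = resp[:, j]
        obs = u >= 0
        if obs.any():
            LL[obs] += logP[:, u[obs]].T
    return LL


def eap_scores(
    resp: np.ndarray,
    items: Sequence[ItemParameters],
    grid: LatentGrid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised EAP mean and SD for every row of a response matrix.

    The prior is standard normal; missing responses are omitted from the
    posterior, so an all-missing row returns the prior moments.
    """
    grid = grid or LatentGrid.default()
    resp = np.atleast_2d(np.asarray(resp, dtype=int))
    log_tables = [
        np.log(_prob_table(it.discrimination, it.thresholds, grid.nodes)[0])
        for it in items
    ]
    for j, it in enumerate(items):
        if resp[:, j].max(initial=-1) >= it.n_categories:
            raise ValueError(f"response out of range for item {j}")
    A = _loglik_matrix(resp, log_tables, len(grid.nodes)) + grid.log_weights()
    A -= _row_logsumexp(A)[:, None]
    post = np.exp(A)
    mean = post @ grid.nodes
    var = post @ grid.nodes**2 - mean**2
    return mean, np.sqrt(np.clip(var, 0.0, None))


def eap_score(
    pattern: Sequence[int],
    items: Sequence[ItemParameters],
    grid: LatentGrid | None = None,
) -> tuple[float, float]:
    """EAP posterior mean and SD for a single response pattern."""
    if len(items) == 0:
        warnings.warn("EAP scoring with no items: returning prior moments")
        return 0.0, 1.0
    mean, sd = eap_scores(np.asarray(pattern, dtype=int)[None, :], items, grid)
    return float(mean[0]), float(sd[0])


def marginal_loglik(
    resp_ref: np.ndarray,
    resp_focal: np.ndarray,
    items_ref: Sequence[ItemParameters],
    items_focal: Sequence[ItemParameters],
    groups: GroupStructure,
    grid: LatentGrid | None = None,
) -> float:
    """Quadrature marginal log-likelihood of two-group response data.

    The reference group is integrated against N(0, 1), the focal group
    against N(focal_mean, focal_variance).
    """
    grid = grid or LatentGrid.default()
    if not groups.focal_variance > 0:
        raise ValueError("focal variance must be positive")
    Q = len(grid.nodes)
    total = 0.0
    for resp, items, (m, s) in (
        (resp_ref, items_ref, (0.0, 1.0)),
        (resp_focal, items_focal, (groups.focal_mean, np.sqrt(groups.focal_variance))),
    ):
        resp = np.atleast_2d(np.asarray(resp, dtype=int))
        log_tables = [
            np.log(_prob_table(it.discrimination, it.thresholds, grid.nodes)[0])
            for it in items
        ]
        A = _loglik_matrix(resp, log_tables, Q) + grid.log_weights(m, s)
        total += float(_row_logsumexp(A).sum())
    return total


@dataclass
class FitResult:
    """Converged (or flagged) multigroup marginal-ML fit.

    ``item_estimates`` maps group label ("reference"/"focal") to a list of
    per-item :class:`ItemParameters` (``None`` for items excluded from the
    likelihood).  Estimates live in the collapsed category space recorded
    by ``category_maps`` (original category labels retained per item).
    """

    item_estimates: dict
    group_estimates: GroupStructure
    log_likelihood: float
    converged: bool
    n_free_parameters: int
    n_iterations: int
    invariant: np.ndarray
    mean_constraint: bool
    category_maps: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def start_values(self) -> dict:
        """Warm-start lookup ``(group, item) -> (a, thresholds)``."""
        out = {}
        for key, label in (("ref", "reference"), ("foc", "focal")):
            for j, it in enumerate(self.item_estimates[label]):
                if it is not None:
                    out[(key, j)] = (it.discrimination, it.thresholds.copy())
        return out


def _category_maps(pooled: np.ndarray):
    """Observed-category relabelling per item from pooled responses.

    Categories with zero pooled observations are collapsed into their
    lower non-empty neighbour so every retained category is populated.
    Returns (maps, n_effective) where maps[j] lists the original labels
    kept for item j.
    """
    J = pooled.shape[1]
    maps, n_eff = [], np.zeros(J, dtype=int)
    for j in range(J):
        u = pooled[:, j]
        u = u[u >= 0]
        if u.size == 0:
            maps.append(np.array([], dtype=int))
            continue
        counts = np.bincount(u)
        present = np.flatnonzero(counts > 0)
        maps.append(present)
        n_eff[j] = present.size
    return maps, n_eff


def _apply_maps(resp: np.ndarray, maps) -> np.ndarray:
    out = resp.copy()
    for j, present in enumerate(maps):
        if present.size == 0:
            continue
        remap = np.full(int(present.max()) + 1, MISSING, dtype=int)
        remap[present] = np.arange(present.size)
        m = out[:, j] >= 0
        out[m, j] = remap[out[m, j]]
    return out


def _start_params(resp_pooled: np.ndarray, j: int, V: int):
    """Default starting values: unit slope, thresholds at the normal
    quantiles of the pooled observed category frequencies."""
    u = resp_pooled[:, j]
    u = u[u >= 0]
    p_ge = np.array([(u >= v).mean() for v in range(1, V)])
    b = _norm.ppf(np.clip(1.0 - p_ge, 1e-4, 1.0 - 1e-4))
    b = np.clip(b, -3.5, 3.5)
    for v in range(1, len(b)):  # enforce strictly increasing start
        b[v] = max(b[v], b[v - 1] + 0.1)
    return 1.0, b


def _pack_block(a: float, b: np.ndarray) -> np.ndarray:
    x = np.empty(len(b) + 1)
    x[0] = np.log(a)
    x[1] = b[0]
    if len(b) > 1:
        x[2:] = np.log(np.clip(np.diff(b), 1e-3, None))
    return x


def _unpack_block(xb: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(xb[0]))
    b = np.empty(len(xb) - 1)
    b[0] = xb[1]
    if len(xb) > 2:
        b[1:] = xb[1] + np.cumsum(np.exp(xb[2:]))
    return a, b


def fit_grm_multigroup(
    resp_ref: np.ndarray,
    resp_focal: np.ndarray,
    invariant: np.ndarray | None = None,
    mean_constraint: bool = False,
    grid: LatentGrid | None = None,
    start: "FitResult | dict | None" = None,
    max_iter: int = 500,
) -> FitResult:
    """Maximise the two-group marginal likelihood under a constraint plan.

    Parameters
    ----------
    resp_ref, resp_focal : int arrays of shape (N_g, J)
        Response matrices; ``MISSING`` (-1) marks missing cells.
    invariant : bool array of shape (J,), optional
        True marks an item whose parameters are shared between groups
        (default: all invariant).
    mean_constraint : bool
        Fix the focal mean at 0 (the focal variance stays free), reducing
        the free-parameter count by exactly one.
    start : FitResult or dict, optional
        Warm start; item values must be in the same collapsed category
        space (i.e. come from a fit of the same dataset).

    The optimiser works on an unconstrained parameterisation (log slope,
    first threshold, log threshold increments; focal mean and log SD) and
    maximises the quadrature marginal log-likelihood directly with
    analytic gradients.
    """
    resp_ref = np.atleast_2d(np.asarray(resp_ref, dtype=int))
    resp_focal = np.atleast_2d(np.asarray(resp_focal, dtype=int))
    if resp_ref.shape[1] != resp_focal.shape[1]:
        raise ValueError("groups must share the same item set")
    J = resp_ref.shape[1]
    grid = grid or LatentGrid.default()
    nodes, Q = grid.nodes, len(grid.nodes)
    if invariant is None:
        invariant = np.ones(J, dtype=bool)
    invariant = np.asarray(invariant, dtype=bool)
    if invariant.shape != (J,):
        raise ValueError("constraint plan length must equal item count")

    pooled = np.vstack([resp_ref, resp_focal])
    maps, n_eff = _category_maps(pooled)
    merged = [j for j in range(J) if 0 < n_eff[j] < int(pooled[:, j].max()) + 1]
    estimable = n_eff >= 2
    r_ref = _apply_maps(resp_ref, maps)
    r_foc = _apply_maps(resp_focal, maps)
    resp_g = (r_ref, r_foc)
    pooled_m = np.vstack([r_ref, r_foc])

    # parameter blocks: one per invariant item, two per group-specific item
    blocks: list[tuple[int, str]] = []
    for j in range(J):
        if not estimable[j]:
            continue
        if invariant[j]:
            blocks.append((j, "both"))
        else:
            blocks.append((j, "ref"))
            blocks.append((j, "foc"))
    sizes = [int(n_eff[j]) for j, _ in blocks]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    n_item_par = int(offsets[-1])
    i_mu = None if mean_constraint else n_item_par
    i_ls = n_item_par + (0 if mean_constraint else 1)
    n_par = i_ls + 1

    start_lookup = {}
    if isinstance(start, FitResult):
        start_lookup = start.start_values()
    elif isinstance(start, dict):
        start_lookup = start

    x0 = np.empty(n_par)
    bounds: list[tuple[float, float]] = []
    for bi, (j, who) in enumerate(blocks):
        V = sizes[bi]
        key = ("ref", j) if who in ("both", "ref") else ("foc", j)
        if key in start_lookup:
            a, b = start_lookup[key]
            if len(b) != V - 1:  # category space mismatch; fall back
                a, b = _start_params(pooled_m, j, V)
        else:
            a, b = _start_params(pooled_m, j, V)
        x0[offsets[bi] : offsets[bi + 1]] = _pack_block(a, np.asarray(b, float))
        bounds.append(_BOUND_LOG_A)
        bounds.append(_BOUND_B1)
        bounds.extend([_BOUND_LOG_D] * (V - 2))
    if not mean_constraint:
        if isinstance(start, FitResult):
            x0[i_mu] = np.clip(start.group_estimates.focal_mean, *_BOUND_MU)
        else:
            x0[i_mu] = 0.0
        bounds.append(_BOUND_MU)
    if isinstance(start, FitResult):
        x0[i_ls] = np.clip(
            0.5 * np.log(start.group_estimates.focal_variance), *_BOUND_LOG_SD
        )
    else:
        x0[i_ls] = 0.0
    bounds.append(_BOUND_LOG_SD)

    lw_ref = grid.log_weights(0.0, 1.0)
    N_foc = r_foc.shape[0]
    group_sel = {"both": (0, 1), "ref": (0,), "foc": (1,)}

    # Blocks sharing a category count are batched so probability tables
    # and gradients are computed in a few large array operations.
    by_V: dict[int, list[int]] = {}
    for bi, V in enumerate(sizes):
        by_V.setdefault(V, []).append(bi)
    batches = []
    block_pos = {}
    for V, bis in sorted(by_V.items()):
        idxmat = np.array(
            [[offsets[bi] + k for k in range(V)] for bi in bis], dtype=int
        )
        for row, bi in enumerate(bis):
            block_pos[bi] = (len(batches), row)
        batches.append((V, bis, idxmat))

    # per (group, item): observed rows, their categories, one-hot matrix
    obs_info = [[None] * J, [None] * J]
    gj_block = [[None] * J, [None] * J]
    for bi, (j, who) in enumerate(blocks):
        if who in ("both", "ref"):
            gj_block[0][j] = bi
        if who in ("both", "foc"):
            gj_block[1][j] = bi
    for g in (0, 1):
        for j in range(J):
            if gj_block[g][j] is None:
                continue
            u = resp_g[g][:, j]
            obs = np.flatnonzero(u >= 0)
            uo = u[obs]
            onehot = np.zeros((obs.size, int(n_eff[j])))
            onehot[np.arange(obs.size), uo] = 1.0
            obs_info[g][j] = (obs, uo, onehot)

    def negloglik(x):
        tabs = []
        for V, bis, idxmat in batches:
            xb = x[idxmat]  # (B, V)
            a = np.exp(xb[:, 0])
            b = np.empty((len(bis), V - 1))
            b[:, 0] = xb[:, 1]
            if V > 2:
                b[:, 1:] = xb[:, 1][:, None] + np.cumsum(
                    np.exp(xb[:, 2:]), axis=1
                )
            C = expit(a[:, None, None] * (nodes[None, :, None] - b[:, None, :]))
            P = np.empty((len(bis), Q, V))
            P[:, :, 0] = 1.0 - C[:, :, 0]
            P[:, :, -1] = C[:, :, -1]
            if V > 2:
                P[:, :, 1:-1] = C[:, :, :-1] - C[:, :, 1:]
            np.clip(P, _MIN_PROB, 1.0, out=P)
            tabs.append((a, b, P, C, np.log(P)))

        mu = 0.0 if mean_constraint else x[i_mu]
        sd = float(np.exp(x[i_ls]))
        lw = (lw_ref, grid.log_weights(mu, sd))

        f = 0.0
        w_g = []
        for g in (0, 1):
            LL = np.zeros((resp_g[g].shape[0], Q))
            for j in range(J):
                info = obs_info[g][j]
                if info is None:
                    continue
                obs, uo, _ = info
                bk, row = block_pos[gj_block[g][j]]
                LL[obs] += tabs[bk][4][row][:, uo].T
            A = LL + lw[g]
            m = _row_logsumexp(A)
            f += m.sum()
            w_g.append(np.exp(A - m[:, None]))

        grad = np.zeros(n_par)
        for bk, (V, bis, idxmat) in enumerate(batches):
            a, b, P, C, _lp = tabs[bk]
            r = np.zeros((len(bis), Q, V))
            for row, bi in enumerate(bis):
                j, who = blocks[bi]
                for g in group_sel[who]:
                    obs, _uo, onehot = obs_info[g][j]
                    r[row] += w_g[g][obs].T @ onehot
            R = r / P
            # dL/dC_k per node, batched over blocks
            S = C * (1.0 - C) * (R[:, :, 1:] - R[:, :, :-1])
            gb = -a[:, None] * S.sum(axis=1)  # (B, V-1)
            ga = a * np.einsum(
                "bqk,bqk->b", S, nodes[None, :, None] - b[:, None, :]
            )
            grad[idxmat[:, 0]] = ga
            grad[idxmat[:, 1]] = gb.sum(axis=1)
            if V > 2:
                d = np.exp(x[idxmat[:, 2:]])
                tail = np.cumsum(gb[:, ::-1], axis=1)[:, ::-1]
                grad[idxmat[:, 2:]] = d * tail[:, 1:]

        W1 = np.exp(lw[1])
        z = nodes - mu
        if not mean_constraint:
            sq = z / sd**2
            grad[i_mu] = float((w_g[1] @ sq).sum() - N_foc * (W1 @ sq))
        tq = z**2 / sd**2
        grad[i_ls] = float((w_g[1] @ tq).sum() - N_foc * (W1 @ tq))
        return -f, -grad

    res = minimize(
        negloglik,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": max_iter,
            "maxfun": 5 * max_iter,
            "ftol": 1e-10,
            "gtol": 1e-5,
        },
    )

    est = {"reference": [None] * J, "focal": [None] * J}
    for bi, (j, who) in enumerate(blocks):
        a, b = _unpack_block(res.x[offsets[bi] : offsets[bi + 1]])
        item = ItemParameters(sizes[bi], a, b)
        if who in ("both", "ref"):
            est["reference"][j] = item
        if who in ("both", "foc"):
            est["focal"][j] = item.copy() if who == "both" else item
    mu_hat = 0.0 if mean_constraint else float(res.x[i_mu])
    var_hat = float(np.exp(2.0 * res.x[i_ls]))

    return FitResult(
        item_estimates=est,
        group_estimates=GroupStructure(mu_hat, var_hat),
        log_likelihood=float(-res.fun),
        converged=bool(res.success),
        n_free_parameters=n_par,
        n_iterations=int(res.nit),
        invariant=invariant.copy(),
        mean_constraint=mean_constraint,
        category_maps=maps,
        diagnostics={
            "merged_items": merged,
            "excluded_items": [j for j in range(J) if not estimable[j]],
            "optimizer_message": str(res.message),
        },
    )


def likelihood_ratio_test(
    general: FitResult, restricted: FitResult
) -> tuple[float, int, float]:
    """Chi-square LRT of a restricted fit against a nesting general fit.

    Returns (statistic, df, p).  Small negative statistics from optimiser
    noise are clipped to zero; negatives beyond 1e-4 trigger a warning
    (but are still clipped so the caller can proceed).
    """
    df = general.n_free_parameters - restricted.n_free_parameters
    if df <= 0:
        raise ValueError("restricted model must have fewer free parameters")
    stat = -2.0 * (restricted.log_likelihood - general.log_likelihood)
    if stat < 0:
        if stat < -1e-4:
            warnings.warn(
                f"LRT statistic {stat:.3g} is negative beyond tolerance; "
                "check convergence of the nested fits"
            )
        stat = 0.0
    return float(stat), int(df), float(_chi2.sf(stat, df))
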