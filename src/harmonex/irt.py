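"""Unidimensional GPCM fitting and the IRT score crosswalk.

The model is fitted to the joint source+target item matrix by marginal
maximum likelihood with an EM algorithm: the latent trait is integrated
out over a fixed quadrature grid with standard-normal weights (which also
identifies the scale), expected category counts per node are accumulated in
the E-step, and each item's discrimination and thresholds are updated in
the M-step by quasi-Newton maximization of its expected complete-data
log-likelihood from the current parameter values, so the marginal
log-likelihood never decreases.

Harmonization then proceeds in two monotone steps: an expected a
posteriori (EAP) trait estimate from the source items alone, followed by
the model-expected target sum score at that trait level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .gpcm import expected_sum_score, gpcm_prob_matrix
from .types import ItemParameters, ResponseDataset, ScaleDefinition

__all__ = [
    "GPCMFit",
    "TraitEstimates",
    "fit_gpcm",
    "eap_theta",
    "expected_sum_score",
    "irt_harmonize",
    "irt_crosswalk",
]

QUAD_POINTS = 61
QUAD_RANGE = (-6.0, 6.0)


def _quadrature(n_points: int = QUAD_POINTS, rng: tuple[float, float] = QUAD_RANGE):
    nodes = np.linspace(rng[0], rng[1], n_points)
    w = norm.pdf(nodes)
    return nodes, w / w.sum()


@dataclass
class GPCMFit:
    """Result of a marginal-ML GPCM fit.

    ``category_values`` is only populated for items fitted with a collapsed
    category: it maps item id to the surviving original score values, used
    when recoding new responses and when computing expected sum scores.
    """

    item_bank: tuple[ItemParameters, ...]
    nodes: np.ndarray
    weights: np.ndarray
    log_likelihood: list[float]
    converged: bool
    n_iter: int
    category_values: dict[str, np.ndarray] = field(default_factory=dict)

    def scale(self, item_ids: list[str], name: str = "fitted") -> ScaleDefinition:
        """Extract a sub-bank (e.g. the source or target items) by id."""
        by_id = {it.item_id: it for it in self.item_bank}
        return ScaleDefinition(name=name, items=tuple(by_id[i] for i in item_ids))


@dataclass
class TraitEstimates:
    """EAP trait estimates and posterior SDs, one per person."""

    eap: np.ndarray
    posterior_sd: np.ndarray


def _expected_ll_and_grad(params: np.ndarray, nodes: np.ndarray, R: np.ndarray):
    """Negative expected complete-data log-likelihood for one item.

    ``R[q, k]`` are expected counts of category k at quadrature node q.
    """
    a, b = params[0], params[1:]
    K = b.size + 1
    steps = a * (nodes[:, None] - b[None, :])
    z = np.concatenate([np.zeros((nodes.size, 1)), np.cumsum(steps, axis=1)], axis=1)
    zmax = z.max(axis=1, keepdims=True)
    logD = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    logP = z - logD[:, None]
    P = np.exp(logP)
    f = float((R * logP).sum())

    # T[q, k] = sum_{v<=k} (theta_q - b_v); dlogP_k/da = T_k - E_P[T]
    T = np.concatenate(
        [np.zeros((nodes.size, 1)), np.cumsum(nodes[:, None] - b[None, :], axis=1)],
        axis=1,
    )
    Nq = R.sum(axis=1)
    grad_a = float((R * T).sum() - (Nq * (P * T).sum(axis=1)).sum())
    # survival S[q, v] = P(X >= v); C[q, v] = expected count of X >= v
    S = P[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:]
    C = R[:, ::-1].cumsum(axis=1)[:, ::-1][:, 1:]
    grad_b = -a * (C - Nq[:, None] * S).sum(axis=0)
    return -f, -np.concatenate([[grad_a], grad_b])


def _start_values(x: np.ndarray, K: int) -> np.ndarray:
    """a = 1; thresholds at normal quantiles implied by the cumulative
    observed category proportions."""
    props = np.bincount(x, minlength=K) / x.size
    cum = np.clip(np.cumsum(props)[:-1], 0.01, 0.99)
    return np.concatenate([[1.0], norm.ppf(cum)])


def fit_gpcm(
    responses: np.ndarray,
    item_ids: list[str] | None = None,
    n_categories: int = 3,
    tol: float = 1e-4,
    max_iter: int = 500,
    n_quadrature: int = QUAD_POINTS,
    on_empty_category: str = "error",
) -> GPCMFit:
    """Fit the unidimensional GPCM to an n x m response matrix.

    Parameters
    ----------
    responses
        Complete integer responses in ``{0, .., n_categories - 1}``.
    item_ids
        Labels for the fitted items (defaults to ``item_1..item_m``).
    tol
        Convergence: maximum absolute parameter change between EM cycles.
    on_empty_category
        ``"error"`` (default) fails with the offending item named when a
        category is unobserved; ``"collapse"`` merges an empty category
        into its lower neighbor for fitting (the fitted item then carries
        one threshold fewer and scoring uses the collapsed category
        values).
    """
    x = np.asarray(responses, dtype=int)
    if x.ndim != 2:
        raise ValueError("responses must be an n x m matrix")
    if x.min() < 0 or x.max() >= n_categories:
        raise ValueError(
            f"responses must lie in 0..{n_categories - 1}, "
            f"observed range [{x.min()}, {x.max()}]"
        )
    n, m = x.shape
    if item_ids is None:
        item_ids = [f"item_{j + 1}" for j in range(m)]

    # per-item category maps (identity unless a category is collapsed)
    cat_values: list[np.ndarray] = []
    recoded = np.empty_like(x)
    for j in range(m):
        observed = np.flatnonzero(np.bincount(x[:, j], minlength=n_categories) > 0)
        if observed.size < 2:
            raise ValueError(
                f"item {item_ids[j]!r} has a single observed category; "
                "cannot estimate its parameters"
            )
        if observed.size < n_categories:
            if on_empty_category == "error":
                raise ValueError(
                    f"item {item_ids[j]!r} has unobserved response categories "
                    f"(observed: {observed.tolist()}); rerun with "
                    "on_empty_category='collapse' to merge them"
                )
            lut = np.searchsorted(observed, np.arange(n_categories)).clip(
                0, observed.size - 1
            )
            recoded[:, j] = lut[x[:, j]]
            cat_values.append(observed.astype(float))
        else:
            recoded[:, j] = x[:, j]
            cat_values.append(np.arange(n_categories, dtype=float))

    nodes, weights = _quadrature(n_quadrature)
    Q = nodes.size
    params = [_start_values(recoded[:, j], cat_values[j].size) for j in range(m)]
    onehots = [
        np.eye(cat_values[j].size, dtype=float)[recoded[:, j]] for j in range(m)
    ]
    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: person x node posterior under current parameters
        A = np.zeros((n, Q))
        logPs = []
        for j in range(m):
            item = ItemParameters(item_ids[j], params[j][0], tuple(params[j][1:]))
            logP = np.log(gpcm_prob_matrix(nodes, item))
            logPs.append(logP)
            A += logP[:, recoded[:, j]].T
        M = A + np.log(weights)[None, :]
        lse = logsumexp(M, axis=1)
        ll_trace.append(float(lse.sum()))
        post = np.exp(M - lse[:, None])

        max_change = 0.0
        for j in range(m):
            R = post.T @ onehots[j]  # Q x K_j
            res = minimize(
                _expected_ll_and_grad,
                params[j],
                args=(nodes, R),
                jac=True,
                method="L-BFGS-B",
                bounds=[(1e-3, 25.0)] + [(-25.0, 25.0)] * (params[j].size - 1),
            )
            new = res.x
            max_change = max(max_change, float(np.abs(new - params[j]).max()))
            params[j] = new
        if max_change < tol:
            converged = True
            break

    items = []
    collapsed: dict[str, np.ndarray] = {}
    for j in range(m):
        items.append(
            ItemParameters(item_ids[j], float(params[j][0]), tuple(params[j][1:]))
        )
        if cat_values[j].size < n_categories:
            collapsed[item_ids[j]] = cat_values[j]
    return GPCMFit(
        item_bank=tuple(items),
        nodes=nodes,
        weights=weights,
        log_likelihood=ll_trace,
        converged=converged,
        n_iter=it,
        category_values=collapsed,
    )


def eap_theta(
    responses: np.ndarray,
    items: ScaleDefinition | tuple[ItemParameters, ...],
    n_quadrature: int = QUAD_POINTS,
) -> TraitEstimates:
    """Expected a posteriori trait estimates under a N(0, 1) prior.

    The posterior over the quadrature grid is proportional to
    ``w_q * L(responses | theta_q)``; the EAP is its mean and
    ``posterior_sd`` its standard deviation.  An empty response pattern
    returns the prior (EAP 0, SD 1).
    """
    item_list = items.items if isinstance(items, ScaleDefinition) else tuple(items)
    x = np.asarray(responses, dtype=int)
    if x.ndim != 2 or (item_list and x.shape[1] != len(item_list)):
        raise ValueError(
            f"responses must be n x {len(item_list)}, got shape {x.shape}"
        )
    n = x.shape[0]
    if len(item_list) == 0:
        return TraitEstimates(eap=np.zeros(n), posterior_sd=np.ones(n))
    nodes, weights = _quadrature(n_quadrature)
    A = np.zeros((n, nodes.size))
    for j, item in enumerate(item_list):
        if x[:, j].min() < 0 or x[:, j].max() >= item.n_categories:
            raise ValueError(
                f"item {item.item_id!r}: response categories must lie in "
                f"0..{item.n_categories - 1}"
            )
        logP = np.log(gpcm_prob_matrix(nodes, item))
        A += logP[:, x[:, j]].T
    M = A + np.log(weights)[None, :]
    post = np.exp(M - logsumexp(M, axis=1)[:, None])
    eap = post @ nodes
    second = post @ (nodes**2)
    psd = np.sqrt(np.maximum(second - eap**2, 0.0))
    return TraitEstimates(eap=eap, posterior_sd=psd)


def irt_harmonize(
    train: ResponseDataset,
    test_source: np.ndarray,
    fit: GPCMFit | None = None,
    **fit_kwargs,
) -> np.ndarray:
    """The full IRT crosswalk: fit on the training fold's joint item data,
    then EAP from the source items and expected target sum score.

    Returns real-valued predicted target sums for the test persons.
    """
    n_src = train.source_responses.shape[1]
    if fit is None:
        joint = np.hstack([train.source_responses, train.target_responses])
        ids = [f"src_{j + 1}" for j in range(n_src)] + [
            f"tgt_{j + 1}" for j in range(train.target_responses.shape[1])
        ]
        fit = fit_gpcm(joint, item_ids=ids, **fit_kwargs)
    src_items = fit.item_bank[:n_src]
    tgt_items = fit.item_bank[n_src:]
    test = np.asarray(test_source, dtype=int).copy()
    for j, item in enumerate(src_items):
        vals = fit.category_values.get(item.item_id)
        if vals is not None:
            # map each original category to the nearest surviving one
            lut = np.abs(np.arange(3)[:, None] - vals[None, :]).argmin(axis=1)
            test[:, j] = lut[test[:, j]]
    est = eap_theta(test, src_items)
    return np.asarray(
        expected_sum_score(est.eap, tgt_items, category_values=fit.category_values)
    )


def irt_crosswalk(
    source_items: ScaleDefinition,
    target_items: ScaleDefinition,
    by: str = "pattern",
) -> "pd.DataFrame":
    """Tabulate the IRT concordance for every source response pattern, or
    per source sum score by pattern-averaging with model-implied weights.
    """
    import itertools

    import pandas as pd

    K = source_items.n_categories
    patterns = np.array(
        list(itertools.product(range(K), repeat=source_items.n_items)), dtype=int
    )
    est = eap_theta(patterns, source_items)
    pred = np.asarray(expected_sum_score(est.eap, target_items))
    nodes, weights = _quadrature()
    # marginal pattern probabilities under the prior
    logL = np.zeros((patterns.shape[0], nodes.size))
    for j, item in enumerate(source_items.items):
        logP = np.log(gpcm_prob_matrix(nodes, item))
        logL += logP[:, patterns[:, j]].T
    p_pattern = np.exp(logsumexp(logL + np.log(weights)[None, :], axis=1))
    df = pd.DataFrame(
        {
            "source_sum": patterns.sum(axis=1),
            "eap": est.eap,
            "harmonized_target_score": pred,
            "pattern_probability": p_pattern,
            "pattern": ["".join(map(str, row)) for row in patterns],
        }
    )
    if by == "pattern":
        return df.sort_values(["source_sum", "pattern"]).reset_index(drop=True)
    if by == "sum":
        out = (
            df.groupby("source_sum")
            .apply(
                lambda g: np.average(
                    g["harmonized_target_score"], weights=g["pattern_probability"]
                ),
                include_groups=False,
            )
            .rename("harmonized_target_score")
            .reset_index()
        )
        return out
    raise ValueError(f"by must be 'pattern' or 'sum', got {by!r}")
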