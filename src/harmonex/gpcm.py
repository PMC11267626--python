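"""Generalized partial credit model (GPCM) response probabilities.

For an item with discrimination ``a`` and thresholds ``b_1..b_{K-1}`` the
probability of category ``k`` (0-based) at trait level ``theta`` is

    P(X = k | theta)  propto  exp( sum_{v<=k} a * (theta - b_v) ),

with an empty sum for ``k = 0``.  A threshold ``b_k`` is the trait value at
which categories ``k-1`` and ``k`` are equally probable.
"""

from __future__ import annotations

import numpy as np

from .types import ItemParameters, ScaleDefinition

__all__ = [
    "gpcm_category_probs",
    "gpcm_prob_matrix",
    "expected_item_score",
    "expected_sum_score",
]


def gpcm_category_probs(theta: float, item: ItemParameters) -> np.ndarray:
    """Category probability vector (length K) for one person on one item.

    Raises ``ValueError`` for non-finite ``theta``; invalid item parameters
    are rejected by :class:`~harmonex.types.ItemParameters` itself.
    """
    theta = float(theta)
    if not np.isfinite(theta):
        raise ValueError(f"theta must be finite, got {theta}")
    return gpcm_prob_matrix(np.array([theta]), item)[0]


def gpcm_prob_matrix(thetas: np.ndarray, item: ItemParameters) -> np.ndarray:
    """Vectorized category probabilities: shape ``(len(thetas), K)``."""
    thetas = np.asarray(thetas, dtype=float)
    b = np.asarray(item.thresholds)
    # cumulative logits: z_k = sum_{v<=k} a (theta - b_v), z_0 = 0
    steps = item.discrimination * (thetas[:, None] - b[None, :])
    z = np.concatenate([np.zeros((thetas.shape[0], 1)), np.cumsum(steps, axis=1)], axis=1)
    z -= z.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    return p


def expected_item_score(
    thetas: np.ndarray,
    item: ItemParameters,
    category_values: np.ndarray | None = None,
) -> np.ndarray:
    """E[X | theta] = sum_k v_k * P(k | theta); non-decreasing in theta.

    ``category_values`` defaults to ``0..K-1``; items fitted with a
    collapsed (unobserved) category pass the surviving score values here.
    """
    p = gpcm_prob_matrix(np.atleast_1d(thetas), item)
    v = (
        np.arange(item.n_categories, dtype=float)
        if category_values is None
        else np.asarray(category_values, dtype=float)
    )
    return p @ v


def expected_sum_score(
    theta,
    scale: ScaleDefinition,
    category_values: dict[str, np.ndarray] | None = None,
) -> np.ndarray | float:
    """Model-expected sum score over an item bank at trait level(s) theta.

    Strictly increasing in theta and bounded by the scale's sum range; this
    is the second half of the IRT crosswalk (trait -> target-scale score).
    """
    items = scale.items if isinstance(scale, ScaleDefinition) else tuple(scale)
    arr = np.atleast_1d(np.asarray(theta, dtype=float))
    total = np.zeros_like(arr)
    for item in items:
        vals = None if category_values is None else category_values.get(item.item_id)
        total += expected_item_score(arr, item, category_values=vals)
    if np.isscalar(theta) or np.ndim(theta) == 0:
        return float(total[0])
    return total
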