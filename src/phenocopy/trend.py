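"""Isotonic dose-response trend testing.

A gene responds dose-dependently when its values across ordered concentration
groups are better explained by a monotone fit than by a flat one.  The
statistic is

    E^2 = (SS0 - SS_iso) / SS0,

where SS0 = sum (y - ybar)^2 and SS_iso is the residual sum of squares of the
least-squares monotone (isotonic) fit; E^2 is computed for both directions and
the maximum taken, giving a two-sided trend statistic in [0, 1].  Significance
comes from a permutation null: sample-to-dose assignments are shuffled B times
and p = (1 + #{permuted E^2 >= observed}) / (B + 1).

The isotonic fit itself uses the min-max representation of weighted L2
isotonic regression on the dose-group means,

    fit_i = max_{j <= i} min_{l >= i} mean(y_j..y_l),

evaluated with cumulative sums so that millions of small fits (genes x
permutations x 2 directions) reduce to a handful of vectorized array
operations over blocks of k dose levels.  Replicates enter through the group
weights: the isotonic fit on raw observations with tied doses equals the
weighted fit on dose means, and the permutation-invariant total sum of squares
lets E^2 be assembled from group means alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["TrendTestResult", "dose_trend_test", "trend_test_batch", "isotonic_fit_means"]

_TIE_EPS = 1e-12  # permuted statistics within this of the observed count as ties


@dataclass(frozen=True)
class TrendTestResult:
    gene_id: str
    e2_up: float
    e2_down: float
    e2: float
    p_perm: float
    direction: str  # increasing | decreasing


def isotonic_fit_means(means: np.ndarray, weights: np.ndarray, *, increasing: bool = True) -> np.ndarray:
    """Weighted L2 isotonic regression of dose-group means.

    means: (..., k) array of group means; weights: (k,) positive weights.
    Returns the monotone fit of the same shape.
    """
    y = np.asarray(means, dtype=float)
    w = np.asarray(weights, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y)
    fit = _pava_minmax(y, w) if increasing else -_pava_minmax(-y, w)
    return fit[0] if squeeze else fit


def _pava_minmax(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Min-max isotonic (increasing) fit for a batch of rows; y (N, k), w (k,)."""
    n, k = y.shape
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cy = np.concatenate([np.zeros((n, 1)), np.cumsum(y * w, axis=1)], axis=1)
    # block means Av[:, j, l] over doses j..l (inclusive), +inf where j > l
    num = cy[:, None, 1:] - cy[:, :-1, None]          # (N, k, k): [j, l]
    den = cw[None, 1:] - cw[:-1, None]                # (k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        av = num / den[None, :, :]
    av[:, den <= 0] = np.inf
    # M[:, j, i] = min over l >= i of Av[:, j, l]
    m = np.flip(np.minimum.accumulate(np.flip(av, axis=2), axis=2), axis=2)
    # fit_i = max over j <= i of M[:, j, i]
    fit = np.maximum.accumulate(m, axis=1)
    return np.einsum("nii->ni", fit).copy()


def _group_stats(values: np.ndarray, boundaries: np.ndarray, counts: np.ndarray):
    """Group sums/means along the last axis of dose-sorted values."""
    sums = np.add.reduceat(values, boundaries, axis=-1)
    return sums / counts


def trend_test_batch(
    values: np.ndarray,
    dose_index: np.ndarray,
    *,
    B: int = 1000,
    rng: np.random.Generator | None = None,
    chunk: int = 256,
):
    """Permutation trend test for many genes sharing one dose layout.

    values: (G, n) responses per gene; dose_index: (n,) integer dose level per
    sample (levels 0..k-1 in concentration order, >= 3 levels required).
    Permutations are drawn independently per gene.  Returns a dict of arrays:
    e2_up, e2_down, e2, p_perm, direction.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    dose_index = np.asarray(dose_index)
    if rng is None:
        rng = np.random.default_rng(0)
    levels = np.unique(dose_index)
    k = len(levels)
    if k < 3:
        raise ValueError(f"trend test needs >= 3 dose groups, got {k}")
    order = np.argsort(dose_index, kind="stable")
    values = values[:, order]
    sorted_doses = dose_index[order]
    counts = np.array([(sorted_doses == lv).sum() for lv in levels], dtype=float)
    boundaries = np.concatenate([[0], np.cumsum(counts[:-1])]).astype(int)

    n_genes, n = values.shape
    grand = values.mean(axis=1, keepdims=True)
    ss_total = ((values - grand) ** 2).sum(axis=1)

    p_perm = np.ones(n_genes)
    obs_means = _group_stats(values, boundaries, counts)
    e2_up, e2_down = _e2_pair(obs_means, counts, grand[:, 0], ss_total)
    e2_obs = np.maximum(e2_up, e2_down)

    base = np.arange(n)
    for start in range(0, n_genes, chunk):
        stop = min(start + chunk, n_genes)
        g = stop - start
        live = ss_total[start:stop] > 0
        if not live.any():
            continue
        perms = rng.permuted(np.broadcast_to(base, (g, B, n)).copy(), axis=2)
        shuffled = np.take_along_axis(values[start:stop, None, :], perms, axis=2)
        means = _group_stats(shuffled.reshape(g * B, n), boundaries, counts)
        up, down = _e2_pair(
            means,
            counts,
            np.repeat(grand[start:stop, 0], B),
            np.repeat(ss_total[start:stop], B),
        )
        e2p = np.maximum(up, down).reshape(g, B)
        exceed = (e2p >= (e2_obs[start:stop, None] - _TIE_EPS)).sum(axis=1)
        p = (1.0 + exceed) / (B + 1.0)
        p_perm[start:stop] = np.where(live, p, 1.0)

    zero = ss_total == 0
    e2_up[zero] = 0.0
    e2_down[zero] = 0.0
    e2 = np.maximum(e2_up, e2_down)
    direction = np.where(e2_up >= e2_down, "increasing", "decreasing")
    return {
        "e2_up": e2_up,
        "e2_down": e2_down,
        "e2": e2,
        "p_perm": p_perm,
        "direction": direction,
    }


def _e2_pair(means: np.ndarray, counts: np.ndarray, grand: np.ndarray, ss_total: np.ndarray):
    """E^2 in both directions from group means, weights and the invariant SS0.

    SS0 - SS_iso = SSB0 - SSB_iso where SSB are the weighted between-group
    sums of squares about the grand mean / isotonic fit respectively.
    """
    ssb0 = (counts * (means - grand[:, None]) ** 2).sum(axis=1)
    fit_up = _pava_minmax(means, counts)
    fit_down = -_pava_minmax(-means, counts)
    ssb_up = (counts * (means - fit_up) ** 2).sum(axis=1)
    ssb_down = (counts * (means - fit_down) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e2_up = np.where(ss_total > 0, (ssb0 - ssb_up) / ss_total, 0.0)
        e2_down = np.where(ss_total > 0, (ssb0 - ssb_down) / ss_total, 0.0)
    return np.clip(e2_up, 0.0, 1.0), np.clip(e2_down, 0.0, 1.0)


def dose_trend_test(
    responses: Sequence[Sequence[float]],
    *,
    B: int = 1000,
    seed: int = 0,
    gene_id: str = "",
) -> TrendTestResult:
    """Trend test for one gene: responses grouped by ordered concentration.

    ``responses[i]`` holds the replicate values at the i-th (ascending) dose;
    at least 3 dose groups with >= 1 replicate each are required.  A constant
    response (SS0 = 0) yields E^2 = 0 and p = 1 by convention.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in responses]
    if len(groups) < 3:
        raise ValueError(f"trend test needs >= 3 dose groups, got {len(groups)}")
    if any(g.size < 1 for g in groups):
        raise ValueError("every dose group needs >= 1 observation")
    y = np.concatenate(groups)
    dose_index = np.concatenate([np.full(g.size, i) for i, g in enumerate(groups)])
    out = trend_test_batch(y[None, :], dose_index, B=B, rng=np.random.default_rng(seed))
    return TrendTestResult(
        gene_id=gene_id,
        e2_up=float(out["e2_up"][0]),
        e2_down=float(out["e2_down"][0]),
        e2=float(out["e2"][0]),
        p_perm=float(out["p_perm"][0]),
        direction=str(out["direction"][0]),
    )
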