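"""Per-gene two-group contrasts with empirical-Bayes variance moderation.

Every comparison in the workflow is pairwise (treated vs vehicle, stimulated
vs unstimulated, siRNA vs mock), so the model is a two-group contrast per
gene: the log2 ratio is the difference of group means, the pooled residual
variance s_g^2 (d_g degrees of freedom) is shrunk towards a common prior by
the standard empirical-Bayes hierarchy

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

with the prior (d0, s0^2) estimated by matching the first two moments of
log s_g^2 across genes (the moderated-t construction of microarray linear
modelling; the moderated t has d0 + d_g degrees of freedom).  Moderation is
what makes triplicate designs usable: with thousands of genes sharing a noise
scale, the effective degrees of freedom become large.

P-values are two-sided and BH-adjusted per contrast; discrete up/down/none
calls combine the adjusted p with an absolute log2-ratio threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionStudy, get_logger

__all__ = [
    "ContrastSpec",
    "ModeratedFit",
    "fit_contrast",
    "contrast_from_groups",
    "adjust_fdr",
    "volcano_classify",
    "estimate_variance_prior",
]

log = get_logger(__name__)


@dataclass(frozen=True)
class ContrastSpec:
    """A named two-group comparison defined by design-table predicates.

    ``selector_a`` / ``selector_b`` are keyword criteria understood by
    :meth:`SampleRecord.matches` (scalars or predicates per field).  Group A
    minus group B is the reported log2 ratio.
    """

    name: str
    selector_a: Mapping
    selector_b: Mapping


@dataclass(frozen=True)
class ModeratedFit:
    """Variance-prior hyperparameters: d0 (prior df, may be inf) and s0_sq."""

    d0: float
    s0_sq: float


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_variance_prior(s_sq: np.ndarray, df: float) -> ModeratedFit:
    """Moment-match (d0, s0^2) from the sample variances of all genes.

    Uses the distribution of z = log s_g^2 under the scaled-F hierarchy:
    E[z] and Var[z] involve digamma/trigamma of df/2 and d0/2; Var[z] in
    excess of trigamma(df/2) identifies d0, the mean then identifies s0^2.
    Zero variances carry no information about the continuous prior and are
    excluded from estimation (an all-zero input yields d0=inf, s0^2=0: the
    degenerate noise-free limit).
    """
    s_sq = np.asarray(s_sq, dtype=float)
    positive = s_sq[s_sq > 0]
    if positive.size == 0:
        return ModeratedFit(d0=np.inf, s0_sq=0.0)
    z = np.log(positive)
    e_mean = float(np.mean(z))
    dfh = df / 2.0
    if positive.size == 1:
        return ModeratedFit(d0=np.inf, s0_sq=float(np.exp(e_mean - special.digamma(dfh) + np.log(dfh))))
    e_var = float(np.var(z, ddof=1))
    excess = e_var - float(special.polygamma(1, dfh))
    if excess <= 0:
        d0 = np.inf
        s0_sq = np.exp(e_mean - special.digamma(dfh) + np.log(dfh))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = np.exp(
            e_mean
            - special.digamma(dfh)
            + np.log(dfh)
            + special.digamma(d0 / 2.0)
            - np.log(d0 / 2.0)
        )
    return ModeratedFit(d0=float(d0), s0_sq=float(s0_sq))


def contrast_from_groups(
    values_a: np.ndarray,
    values_b: np.ndarray,
    genes: list[str],
    *,
    moderation: bool = True,
    alpha: float = 0.01,
    lr_min: float = 1.0,
    name: str = "contrast",
) -> pd.DataFrame:
    """Core contrast computation on explicit sample groups.

    values_a/values_b: genes x n_A and genes x n_B log2 matrices.
    Returns a DataFrame with columns lr, t, p_raw, p_adj, call (index gene_id).
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError(f"contrast {name!r}: each group needs >= 2 samples (got {n_a}, {n_b})")
    lr = a.mean(axis=1) - b.mean(axis=1)
    df_resid = n_a + n_b - 2
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s_sq = ss / df_resid
    scale = np.sqrt(1.0 / n_a + 1.0 / n_b)

    if moderation:
        prior = estimate_variance_prior(s_sq, df_resid)
        if np.isinf(prior.d0):
            s_tilde_sq = np.full_like(s_sq, prior.s0_sq)
            df_total = np.inf
        else:
            s_tilde_sq = (prior.d0 * prior.s0_sq + df_resid * s_sq) / (prior.d0 + df_resid)
            df_total = prior.d0 + df_resid
    else:
        if np.all(s_sq == 0):
            raise ValueError(
                f"contrast {name!r}: all genes have zero residual variance; "
                "enable moderation"
            )
        s_tilde_sq = s_sq
        df_total = df_resid

    se = np.sqrt(s_tilde_sq) * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lr / se
    # noise-free genes: infinite evidence when the means differ, none otherwise
    zero = se == 0
    t[zero & (lr > 0)] = np.inf
    t[zero & (lr < 0)] = -np.inf
    t[zero & (lr == 0)] = 0.0
    if np.isinf(df_total):
        p_raw = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p_raw = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    p_raw = np.where(zero & (lr != 0), 0.0, p_raw)
    p_raw = np.where(zero & (lr == 0), 1.0, p_raw)

    table = pd.DataFrame({"lr": lr, "t": t, "p_raw": p_raw}, index=pd.Index(genes, name="gene_id"))
    table["p_adj"] = adjust_fdr(table["p_raw"].to_numpy())
    table["call"] = volcano_classify(table, alpha=alpha, lr_min=lr_min)
    return table


def fit_contrast(
    study: ExpressionStudy,
    spec: ContrastSpec,
    *,
    moderation: bool = True,
    alpha: float = 0.01,
    lr_min: float = 1.0,
) -> pd.DataFrame:
    """Fit a two-group contrast on a study; see ``contrast_from_groups``."""
    idx_a = study.select(**spec.selector_a)
    idx_b = study.select(**spec.selector_b)
    if set(idx_a) & set(idx_b):
        raise ValueError(f"contrast {spec.name!r}: selected groups overlap")
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(
            f"contrast {spec.name!r}: each group needs >= 2 samples "
            f"(got {len(idx_a)}, {len(idx_b)})"
        )
    table = contrast_from_groups(
        study.values[:, idx_a],
        study.values[:, idx_b],
        study.genes,
        moderation=moderation,
        alpha=alpha,
        lr_min=lr_min,
        name=spec.name,
    )
    n_up = int((table["call"] == "up").sum())
    n_down = int((table["call"] == "down").sum())
    log.info(
        "contrast %s: n_A=%d n_B=%d genes=%d up=%d down=%d (alpha=%g lr_min=%g)",
        spec.name, len(idx_a), len(idx_b), study.n_genes, n_up, n_down, alpha, lr_min,
    )
    return table


def adjust_fdr(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def volcano_classify(table: pd.DataFrame, *, alpha: float, lr_min: float) -> pd.Series:
    """Discrete regulation calls: up/down when significant and past the LR cut.

    up:   p_adj < alpha and lr >= lr_min
    down: p_adj < alpha and lr <= -lr_min
    With lr_min = 0 any significant gene is called by the sign of its LR
    (genes with lr exactly 0 are never significant and stay 'none').
    """
    sig = table["p_adj"].to_numpy() < alpha
    lr = table["lr"].to_numpy()
    if lr_min > 0:
        up = sig & (lr >= lr_min)
        down = sig & (lr <= -lr_min)
    else:
        up = sig & (lr > 0)
        down = sig & (lr < 0)
    calls = np.where(up, "up", np.where(down, "down", "none"))
    return pd.Series(calls, index=table.index, name="call")
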