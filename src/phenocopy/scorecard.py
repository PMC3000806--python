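"""Multi-criterion compound scorecard.

Compounds are ranked per criterion (average ranks on ties, direction-aware:
for a lower_better criterion the smallest value gets rank 1), rank totals are
summed, and the final order sorts ascending total with alphabetical
tie-breaking.  Rank-sum integration is deliberately scale-free: any monotone
transformation of a criterion's values leaves the ranking unchanged, so
off-target gene counts, pathway counts and IC50s can sit side by side.
For reporting, each rank is bucketed into tertiles (blue / white / red).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core_io import get_logger

__all__ = ["Criterion", "Scorecard", "build_scorecard", "default_criteria"]

log = get_logger(__name__)

LOWER_BETTER = "lower_better"
HIGHER_BETTER = "higher_better"


@dataclass(frozen=True)
class Criterion:
    name: str
    direction: str  # lower_better | higher_better

    def __post_init__(self) -> None:
        if self.direction not in (LOWER_BETTER, HIGHER_BETTER):
            raise ValueError(f"criterion {self.name!r}: unknown direction {self.direction!r}")


@dataclass
class Scorecard:
    compounds: list[str]
    criteria: list[Criterion]
    values: pd.DataFrame  # compounds x criteria
    ranks: pd.DataFrame  # compounds x criteria, 1 = best, average ties
    total: pd.Series
    final_order: list[str]
    colors: pd.DataFrame  # blue / white / red per cell

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.columns = [f"{c}" for c in out.columns]
        out["rank_total"] = self.total
        out["final_rank"] = [self.final_order.index(c) + 1 for c in out.index]
        return out.loc[self.final_order]


def build_scorecard(
    metrics: pd.DataFrame, criteria: Sequence[Criterion] | Mapping[str, str]
) -> Scorecard:
    """Rank a compounds x criteria metric table into a scorecard.

    ``metrics`` must be numeric with no missing cells; ``criteria`` is either
    an ordered sequence of Criterion or a mapping name -> direction covering
    every column used.
    """
    if isinstance(criteria, Mapping):
        criteria = [Criterion(name, direction) for name, direction in criteria.items()]
    names = [c.name for c in criteria]
    missing_cols = [n for n in names if n not in metrics.columns]
    if missing_cols:
        raise ValueError(f"metrics table lacks criteria columns {missing_cols}")
    values = metrics[names].copy()
    for col in names:
        column = values[col]
        if column.isna().any():
            offender = column.index[column.isna()][0]
            raise ValueError(f"missing value for compound {offender!r}, criterion {col!r}")
        if not np.issubdtype(column.dtype, np.number):
            raise ValueError(f"criterion {col!r} is not numeric")

    ranks = pd.DataFrame(index=values.index, columns=names, dtype=float)
    for crit in criteria:
        v = values[crit.name].to_numpy(dtype=float)
        ranks[crit.name] = rankdata(v if crit.direction == LOWER_BETTER else -v, method="average")
    total = ranks.sum(axis=1)
    final_order = sorted(values.index, key=lambda c: (total[c], c))

    n = len(values.index)
    colors = ranks.copy().astype(object)
    for col in names:
        tert = np.ceil(3 * ranks[col].to_numpy() / n)
        colors[col] = np.where(tert <= 1, "blue", np.where(tert <= 2, "white", "red"))

    log.info(
        "scorecard: %d compounds x %d criteria, best=%s",
        n, len(names), final_order[0] if final_order else None,
    )
    return Scorecard(
        compounds=list(values.index),
        criteria=list(criteria),
        values=values,
        ranks=ranks,
        total=total,
        final_order=list(final_order),
        colors=colors,
    )


def default_criteria(
    *,
    off_target_counts: Mapping[str, Mapping[float, int]],
    counter_therapeutic: Mapping[str, int],
    n_significant_sets: Mapping[str, int],
    n_toxicity_sets: Mapping[str, int] | None = None,
    n_inflammation_sets: Mapping[str, int] | None = None,
    n_off_target_kinases: Mapping[str, int] | None = None,
    potency: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[Criterion]]:
    """Assemble the standard metric table from pipeline outputs.

    off_target_counts: compound -> {time_h: count}; a pooled total column is
    added.  Toxicity/inflammation-tagged set counts and kinase counts are
    optional (omitted with a warning when absent); potency columns
    (biochemical/cellular IC50) are user-supplied wet-lab inputs, ranked
    lower_better.  All assembled criteria are lower_better: fewer off-target
    genes, fewer counter-therapeutic genes, fewer affected pathways, fewer
    off-target kinases and lower IC50s make a better compound.
    """
    compounds = sorted(off_target_counts)
    rows: dict[str, dict[str, float]] = {c: {} for c in compounds}
    times = sorted({t for counts in off_target_counts.values() for t in counts})
    for c in compounds:
        for t in times:
            if t not in off_target_counts[c]:
                raise ValueError(f"compound {c!r}: no off-target count at t={t:g}")
            rows[c][f"off_target_genes_{t:g}h"] = off_target_counts[c][t]
        rows[c]["off_target_genes_total"] = sum(off_target_counts[c].values())
        if c not in counter_therapeutic:
            raise ValueError(f"compound {c!r}: counter-therapeutic count missing")
        rows[c]["counter_therapeutic_genes"] = counter_therapeutic[c]
        if c not in n_significant_sets:
            raise ValueError(f"compound {c!r}: significant gene-set count missing")
        rows[c]["affected_gene_sets"] = n_significant_sets[c]

    def optional(name: str, mapping: Mapping[str, int] | None) -> None:
        if mapping is None:
            log.warning("default_criteria: %s not supplied, criterion omitted", name)
            return
        for c in compounds:
            if c not in mapping:
                raise ValueError(f"compound {c!r}: {name} missing")
            rows[c][name] = mapping[c]

    optional("toxicity_gene_sets", n_toxicity_sets)
    optional("inflammation_gene_sets", n_inflammation_sets)
    optional("off_target_kinases", n_off_target_kinases)

    metrics = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    if potency is not None:
        missing = set(metrics.index) - set(potency.index)
        if missing:
            raise ValueError(f"potency table missing compounds {sorted(missing)}")
        metrics = metrics.join(potency.loc[metrics.index])
    criteria = [Criterion(name, LOWER_BETTER) for name in metrics.columns]
    return metrics, criteria
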