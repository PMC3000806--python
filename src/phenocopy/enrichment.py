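"""Fisher's-exact gene-set enrichment and pathway-profile clustering.

Enrichment of a query signature against a gene-set collection uses the
one-sided hypergeometric tail: with a universe of N genes, a set of K, a
query of n and an overlap of k, p = P(X >= k) for X ~ Hypergeom(N, K, n).
For universes up to 10^4 genes the tail is summed in exact rational
arithmetic before conversion to float; larger universes fall back to the
scipy survival function.  Significance is thresholded on -log10 p (default
threshold 2, i.e. raw p < 0.01 per set); no correction across sets is applied
by default, with BH available as an option.

Condition-by-pathway -log10 p matrices keep only rows significant somewhere
and are ordered by hierarchical clustering with manhattan distance and
complete linkage, the same geometry used for treatment signatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import GeneSet, get_logger
from .diffexp import adjust_fdr
from .signatures import linkage_to_newick

__all__ = [
    "EnrichmentRecord",
    "fisher_enrichment",
    "enrich_signature",
    "enrichment_matrix",
    "cluster_enrichment",
    "hypergeom_tail_p",
]

log = get_logger(__name__)

_EXACT_UNIVERSE_LIMIT = 10_000


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    odds_ratio: float
    p_raw: float
    neg_log10_p: float
    significant: bool


def hypergeom_tail_p(overlap: int, set_size: int, query_size: int, universe_size: int) -> float:
    """P(X >= overlap) for X ~ Hypergeom(universe, set, query draws).

    Exact rational summation for universes up to 10^4; scipy tail otherwise.
    """
    if not 0 <= overlap <= min(set_size, query_size):
        raise ValueError("overlap must be within [0, min(set_size, query_size)]")
    if universe_size <= _EXACT_UNIVERSE_LIMIT:
        denom = math.comb(universe_size, query_size)
        total = sum(
            math.comb(set_size, k) * math.comb(universe_size - set_size, query_size - k)
            for k in range(overlap, min(set_size, query_size) + 1)
            if query_size - k <= universe_size - set_size
        )
        return float(Fraction(total, denom))
    return float(stats.hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def fisher_enrichment(
    query: Iterable[str],
    gene_set: GeneSet,
    universe: Iterable[str],
    *,
    threshold: float = 2.0,
) -> EnrichmentRecord:
    """One-sided enrichment of a query gene list in one gene set.

    The gene set is intersected with the universe before testing; the query
    must be a subset of the universe.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    if not query_set:
        raise ValueError("empty query")
    stray = query_set - universe_set
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}...")
    members = set(gene_set.members) & universe_set
    overlap = len(query_set & members)
    n_univ, n_set, n_query = len(universe_set), len(members), len(query_set)
    p = hypergeom_tail_p(overlap, n_set, n_query, n_univ) if n_set else 1.0
    a = overlap
    b = n_query - overlap
    c = n_set - overlap
    d = n_univ - n_set - b
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    neg_log = -math.log10(p) if p > 0 else float("inf")
    return EnrichmentRecord(
        set_name=gene_set.name,
        overlap=overlap,
        set_size=n_set,
        query_size=n_query,
        universe_size=n_univ,
        odds_ratio=odds,
        p_raw=p,
        neg_log10_p=neg_log,
        significant=neg_log > threshold,
    )


def enrich_signature(
    query: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    *,
    threshold: float = 2.0,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Enrichment records for a query against a whole collection.

    With ``bh_correct`` the -log10 values and significance flags are computed
    on BH-adjusted p (off by default: pathway heat maps conventionally
    threshold the raw Fisher p).
    """
    universe_set = set(universe)
    records = [
        fisher_enrichment(query, gs, universe_set, threshold=threshold) for gs in gene_sets
    ]
    frame = pd.DataFrame([r.__dict__ for r in records]).set_index("set_name")
    if bh_correct and len(frame):
        frame["p_adj"] = adjust_fdr(frame["p_raw"].to_numpy())
        with np.errstate(divide="ignore"):
            frame["neg_log10_p"] = -np.log10(frame["p_adj"])
        frame["significant"] = frame["neg_log10_p"] > threshold
    n_sig = int(frame["significant"].sum()) if len(frame) else 0
    log.info(
        "enrichment: query=%d sets=%d significant=%d (threshold %g)",
        len(set(query)), len(gene_sets), n_sig, threshold,
    )
    return frame


def enrichment_matrix(
    signatures: Mapping[str, Iterable[str]],
    gene_sets: Sequence[GeneSet],
    universe: Iterable[str],
    *,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """-log10 p matrix (gene sets x conditions), rows significant somewhere.

    Column order follows the input mapping; row order follows the collection.
    Conditions with empty signatures contribute a column of zeros.
    """
    if not signatures:
        raise ValueError("need >= 1 signature")
    universe_set = set(universe)
    columns = {}
    sig_flags = {}
    for label, query in signatures.items():
        query = set(query)
        if query:
            frame = enrich_signature(query, gene_sets, universe_set, threshold=threshold)
            columns[label] = frame["neg_log10_p"]
            sig_flags[label] = frame["significant"]
        else:
            idx = pd.Index([gs.name for gs in gene_sets], name="set_name")
            columns[label] = pd.Series(0.0, index=idx)
            sig_flags[label] = pd.Series(False, index=idx)
    matrix = pd.DataFrame(columns)
    keep = pd.DataFrame(sig_flags).any(axis=1)
    result = matrix.loc[keep]
    log.info(
        "enrichment_matrix: %d conditions, %d/%d sets significant somewhere",
        len(signatures), int(keep.sum()), len(gene_sets),
    )
    return result


@dataclass
class EnrichmentClustering:
    matrix: pd.DataFrame  # reordered
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_newick: str | None
    col_newick: str | None


def cluster_enrichment(matrix: pd.DataFrame, *, cluster_columns: bool = True) -> EnrichmentClustering:
    """Order an enrichment matrix by hierarchical clustering of its rows
    (and optionally columns): manhattan distance, complete linkage."""
    if matrix.shape[0] < 1:
        raise ValueError("empty enrichment matrix")
    if matrix.shape[0] == 1:
        log.warning("cluster_enrichment: single row, identity ordering")
        return EnrichmentClustering(matrix.copy(), None, None, None, None)
    row_z = hierarchy.linkage(pdist(matrix.to_numpy(), metric="cityblock"), method="complete")
    row_order = hierarchy.leaves_list(row_z)
    col_z = None
    col_order = np.arange(matrix.shape[1])
    if cluster_columns and matrix.shape[1] > 1:
        col_z = hierarchy.linkage(
            pdist(matrix.to_numpy().T, metric="cityblock"), method="complete"
        )
        col_order = hierarchy.leaves_list(col_z)
    ordered = matrix.iloc[row_order, col_order]
    return EnrichmentClustering(
        matrix=ordered,
        row_linkage=row_z,
        col_linkage=col_z,
        row_newick=linkage_to_newick(row_z, list(matrix.index)),
        col_newick=(
            linkage_to_newick(col_z, list(matrix.columns)) if col_z is not None else None
        ),
    )
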