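"""Kinase-panel selectivity deconvolution and surrogate-marker overlay.

Single-point biochemical panels report percent inhibition of each kinase at
two compound concentrations.  A kinase counts as an off-target of a compound
when it is inhibited by at least 90% at 2 uM AND at least 50% at 200 nM
(boundaries inclusive; negative values — apparent activation — are legal and
simply fail).  Selected kinases are then connected to the transcriptome: each
kinase carries a literature-annotated set of downstream surrogate-marker
genes, and markers that appear in the compound's off-target signature are
evidence that the kinase is functionally inhibited in the cellular system.
A marker shared by several selected kinases cannot discriminate between them
and flags all of them as ambiguous.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .core_io import get_logger

__all__ = [
    "KinaseEvidence",
    "read_panel",
    "write_panel",
    "read_surrogate_map",
    "write_surrogate_map",
    "select_off_target_kinases",
    "surrogate_overlay",
    "coverage_summary",
]

log = get_logger(__name__)

PANEL_COLUMNS = ("kinase_id", "compound_id", "inhibition_2uM", "inhibition_200nM")
THRESHOLD_2UM = 90.0
THRESHOLD_200NM = 50.0


@dataclass(frozen=True)
class KinaseEvidence:
    kinase_id: str
    selected: bool
    n_markers: int
    n_markers_regulated: int
    regulated_marker_ids: tuple[str, ...]
    ambiguous: bool
    marker_ids: tuple[str, ...] = ()  # full described-marker set of the kinase


def read_panel(path: str | Path) -> pd.DataFrame:
    """Panel CSV: kinase_id, compound_id, inhibition_2uM, inhibition_200nM."""
    panel = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(panel.columns)
    if missing:
        raise ValueError(f"{path}: panel missing columns {sorted(missing)}")
    dup = panel.duplicated(subset=["kinase_id", "compound_id"])
    if dup.any():
        pairs = panel.loc[dup, ["kinase_id", "compound_id"]].to_records(index=False)
        raise ValueError(f"{path}: duplicate (kinase, compound) records: {list(pairs)[:5]}")
    for col in ("inhibition_2uM", "inhibition_200nM"):
        bad = (panel[col] < -50) | (panel[col] > 110)
        if bad.any():
            raise ValueError(f"{path}: {col} outside [-50, 110] for {int(bad.sum())} rows")
    return panel[list(PANEL_COLUMNS)]


def write_panel(panel: pd.DataFrame, path: str | Path) -> None:
    panel[list(PANEL_COLUMNS)].to_csv(path, index=False)


def read_surrogate_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Surrogate map TSV: kinase_id TAB gene_id, one pair per line.

    A kinase may appear with an empty gene field to declare that it has no
    described markers.
    """
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                mapping.setdefault(fields[0], set())
            elif len(fields) == 2:
                kin, gene = fields
                mapping.setdefault(kin, set())
                if gene:
                    mapping[kin].add(gene)
            else:
                raise ValueError(f"{path}:{lineno}: expected 'kinase<TAB>gene'")
    return {k: frozenset(v) for k, v in mapping.items()}


def write_surrogate_map(mapping: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for kin in sorted(mapping):
            members = sorted(mapping[kin])
            if not members:
                fh.write(f"{kin}\t\n")
            for gene in members:
                fh.write(f"{kin}\t{gene}\n")


def select_off_target_kinases(panel: pd.DataFrame, compound: str) -> list[str]:
    """Kinases inhibited >= 90% at 2 uM and >= 50% at 200 nM (inclusive)."""
    rows = panel[panel["compound_id"] == compound]
    if rows.empty:
        raise ValueError(f"compound {compound!r} absent from the panel")
    selected = rows[
        (rows["inhibition_2uM"] >= THRESHOLD_2UM)
        & (rows["inhibition_200nM"] >= THRESHOLD_200NM)
    ]["kinase_id"]
    result = sorted(selected)
    log.info(
        "select_off_target_kinases %s: %d of %d kinases pass (>=%g%% @2uM and >=%g%% @200nM)",
        compound, len(result), rows["kinase_id"].nunique(), THRESHOLD_2UM, THRESHOLD_200NM,
    )
    return result


def surrogate_overlay(
    selected_kinases: Iterable[str],
    surrogate_map: Mapping[str, Iterable[str]],
    off_target_genes: Iterable[str],
    expressed_kinases: Iterable[str] | None = None,
) -> list[KinaseEvidence]:
    """Overlay selected kinases' surrogate markers with an off-target signature.

    Only kinases expressed in the cellular system are considered (default:
    all selected kinases).  Kinases without described markers are reported
    with n_markers = 0.  A regulated marker mapping to more than one selected
    kinase marks all its kinases ambiguous.
    """
    selected = list(dict.fromkeys(selected_kinases))
    expressed = set(selected) if expressed_kinases is None else set(expressed_kinases)
    off_genes = set(off_target_genes)
    considered = [k for k in selected if k in expressed]

    regulated_by_kinase = {
        k: sorted(set(surrogate_map.get(k, ())) & off_genes) for k in considered
    }
    marker_owners: dict[str, int] = {}
    for k in considered:
        for gene in regulated_by_kinase[k]:
            marker_owners[gene] = marker_owners.get(gene, 0) + 1

    evidence = []
    for k in considered:
        markers = sorted(set(surrogate_map.get(k, ())))
        regulated = regulated_by_kinase[k]
        evidence.append(
            KinaseEvidence(
                kinase_id=k,
                selected=True,
                n_markers=len(markers),
                n_markers_regulated=len(regulated),
                regulated_marker_ids=tuple(regulated),
                ambiguous=any(marker_owners[g] > 1 for g in regulated),
                marker_ids=tuple(markers),
            )
        )
    n_amb = sum(ev.ambiguous for ev in evidence)
    log.info(
        "surrogate_overlay: %d kinases considered, %d with regulated markers, %d ambiguous",
        len(evidence), sum(ev.n_markers_regulated > 0 for ev in evidence), n_amb,
    )
    return evidence


def coverage_summary(
    evidence: Iterable[KinaseEvidence], off_target_genes: Iterable[str]
) -> dict:
    """Marker coverage of an off-target signature across selected kinases.

    Returns n_markers_total (distinct described markers over all selected
    kinases), n_markers_regulated (those in the off-target signature), and
    pct_regulated = 100 * regulated / total truncated to one decimal
    (None when no markers are described).  Truncation (round toward zero) is
    the convention these panel reports use for marker coverage: 84 of 366
    reads 22.9%, not 23.0%.
    """
    off_genes = set(off_target_genes)
    markers: set[str] = set()
    for ev in evidence:
        markers.update(ev.marker_ids)
    regulated = markers & off_genes
    if markers:
        exact = decimal.Decimal(100 * len(regulated)) / decimal.Decimal(len(markers))
        pct = float(exact.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_DOWN))
    else:
        pct = None
    summary = {
        "n_markers_total": len(markers),
        "n_markers_regulated": len(regulated),
        "pct_regulated": pct,
    }
    log.info("coverage_summary: %s", summary)
    return summary
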