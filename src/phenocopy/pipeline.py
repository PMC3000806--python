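"""End-to-end orchestration: study -> signatures -> enrichment -> kinases -> scorecard.

This module glues the stages together the way the analysis drivers and the
command-line interface use them, so the whole qualification workflow can be
rerun from one call.  Each stage function returns plain pandas/dataclass
objects and is independently usable; ``run_workflow`` chains them and collects
everything a compound scorecard needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import AnalysisConfig, ExpressionStudy, GeneSet, get_logger
from .enrichment import enrichment_matrix
from .kinaseprof import coverage_summary, select_off_target_kinases, surrogate_overlay
from .scorecard import Scorecard, build_scorecard, default_criteria
from .signatures import (
    OffTargetResult,
    SignatureSet,
    arm_contrast,
    classify_profiles,
    compound_call_pairs,
    counter_therapeutic_count,
    off_target_signature,
    on_target_signature,
)

__all__ = ["WorkflowResult", "run_workflow", "off_target_stage", "on_target_stage"]

log = get_logger(__name__)


@dataclass
class WorkflowResult:
    config: AnalysisConfig
    on_target: dict[float, SignatureSet]
    off_target: dict[str, OffTargetResult]
    counter_therapeutic: dict[str, int]
    profiles: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    kinase_evidence: dict[str, list]
    kinase_coverage: dict[str, dict]
    scorecard: Scorecard | None

    def summary(self) -> dict:
        out: dict = {
            "on_target_sizes": {t: len(s) for t, s in self.on_target.items()},
            "off_target_sizes": {c: len(r.pooled) for c, r in self.off_target.items()},
            "counter_therapeutic": dict(self.counter_therapeutic),
        }
        if self.scorecard is not None:
            out["final_order"] = self.scorecard.final_order
        return out


def on_target_stage(
    study: ExpressionStudy,
    config: AnalysisConfig,
    *,
    times: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
) -> dict[float, SignatureSet]:
    times = study.times() if times is None else list(times)
    rng = config.rng() if rng is None else rng
    return {
        t: on_target_signature(study, study.compounds(), t, config, rng=rng) for t in times
    }


def off_target_stage(
    study: ExpressionStudy,
    config: AnalysisConfig,
    *,
    times: Sequence[float] | None = None,
) -> dict[str, OffTargetResult]:
    results = {}
    for compound in study.compounds():
        pairs = compound_call_pairs(study, compound, config, times=times)
        results[compound] = off_target_signature(pairs, compound, config)
    return results


def run_workflow(
    study: ExpressionStudy,
    config: AnalysisConfig,
    *,
    gene_sets: Sequence[GeneSet] | None = None,
    panel: pd.DataFrame | None = None,
    surrogate_map: Mapping[str, frozenset[str]] | None = None,
    times: Sequence[float] | None = None,
    classify_time: float | None = None,
    toxicity_tags: Sequence[str] = ("TOX",),
    inflammation_tags: Sequence[str] = ("INFLAM",),
) -> WorkflowResult:
    """Run the full qualification workflow on one study.

    gene_sets / panel / surrogate_map are optional: the corresponding stages
    (enrichment criteria, kinase criteria) are skipped when absent.
    ``classify_time`` selects the time point for profile classification
    (default: earliest, where primary responses dominate).
    """
    times = study.times() if times is None else list(times)
    compounds = study.compounds()
    rng = config.rng()

    on_target = on_target_stage(study, config, times=times, rng=rng)
    off_target = off_target_stage(study, config, times=times)

    # compound-alone regulation at the read-out concentrations, for the
    # counter-therapeutic criterion
    counter: dict[str, int] = {}
    reference_time = times[0]
    reference_on = on_target[reference_time]
    for compound in compounds:
        calls = []
        for t in times:
            for conc in config.offtarget_concentrations_uM:
                table = arm_contrast(
                    study, compound, conc, t, stimulated=False, config=config
                )
                calls.append(table["call"])
        counter[compound] = counter_therapeutic_count(reference_on, calls)

    classify_time = reference_time if classify_time is None else classify_time
    profiles = classify_profiles(
        study, classify_time, config, on_target=on_target[classify_time], rng=rng
    )

    enr = None
    n_sig_sets = n_tox = n_inflam = None
    if gene_sets:
        signatures = {c: off_target[c].pooled.genes for c in compounds}
        enr = enrichment_matrix(
            signatures, gene_sets, study.genes, threshold=config.enrichment_threshold
        )
        sig = enr > config.enrichment_threshold
        n_sig_sets = {c: int(sig[c].sum()) for c in compounds}

        def tagged(tags: Sequence[str]) -> dict[str, int] | None:
            if not tags:
                log.warning("no tag list supplied; tagged-set criterion omitted")
                return None
            mask = enr.index.str.startswith(tuple(tags))
            return {c: int(sig.loc[mask, c].sum()) for c in compounds}

        n_tox = tagged(tuple(toxicity_tags))
        n_inflam = tagged(tuple(inflammation_tags))

    kinase_evidence: dict[str, list] = {}
    kinase_coverage: dict[str, dict] = {}
    n_kinases = None
    if panel is not None:
        n_kinases = {}
        expressed = None
        if surrogate_map is not None:
            # default expressed-kinase rule: kinases present as genes in the study
            in_study = set(study.genes) & set(surrogate_map)
            expressed = in_study if in_study else None
        for compound in compounds:
            selected = select_off_target_kinases(panel, compound)
            n_kinases[compound] = len(selected)
            if surrogate_map is not None:
                evidence = surrogate_overlay(
                    selected, surrogate_map, off_target[compound].pooled.genes,
                    expressed_kinases=expressed,
                )
                kinase_evidence[compound] = evidence
                kinase_coverage[compound] = coverage_summary(
                    evidence, off_target[compound].pooled.genes
                )

    card = None
    if n_sig_sets is not None:
        metrics, criteria = default_criteria(
            off_target_counts={
                c: {t: len(off_target[c].per_time[t]) if t in off_target[c].per_time else 0
                    for t in times}
                for c in compounds
            },
            counter_therapeutic=counter,
            n_significant_sets=n_sig_sets,
            n_toxicity_sets=n_tox,
            n_inflammation_sets=n_inflam,
            n_off_target_kinases=n_kinases,
        )
        card = build_scorecard(metrics, criteria)

    return WorkflowResult(
        config=config,
        on_target=on_target,
        off_target=off_target,
        counter_therapeutic=counter,
        profiles=profiles,
        enrichment=enr,
        kinase_evidence=kinase_evidence,
        kinase_coverage=kinase_coverage,
        scorecard=card,
    )
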