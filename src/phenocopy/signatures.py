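"""On-target, siRNA and off-target signature derivation and profile classes.

The on-target (pathway) signature is built per time point by three sequential
filters: (1) genes significantly regulated by stimulation itself (stimulated
vs unstimulated vehicle), (2) of those, genes significantly deregulated by at
least one concentration of a compound under stimulation, (3) of those, genes
whose compound-induced log2 ratios change dose-dependently (isotonic
permutation trend test).  Per-compound survivors are pooled into the common
signature; direction comes from the stimulation response.

The siRNA signature replays the logic with a receptor knockdown: filter-1
genes that respond to the active siRNA but not to a control siRNA.

The off-target signature works on call pairs from the stimulated (tgf) and
unstimulated (wotgf) compound arms at the two read-out concentrations: a gene
belongs to a compound's off-target signature iff, at some concentration and
time, it is significantly regulated in BOTH arms (any sign combination) —
i.e. the regulation does not require the stimulus and is therefore not routed
through the drug target.

A per-(gene, compound) decision tree assigns one of six response-profile
classes (bipolar, common, pure off-target, additive, inverse, pure on-target)
or leaves the gene unclassified; precedence resolves genes matching several
qualitative patterns.  Treatment signatures (all regulated genes per compound
x concentration) are compared by hierarchical clustering of signed log2
ratios with manhattan distance and complete linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core_io import AnalysisConfig, ExpressionStudy, get_logger
from .diffexp import contrast_from_groups
from .trend import TrendTestResult, dose_trend_test, trend_test_batch

__all__ = [
    "RegulationCallPair",
    "SignatureSet",
    "OffTargetResult",
    "TreatmentClustering",
    "TrendTestResult",
    "dose_trend_test",
    "arm_contrast",
    "stimulation_contrast",
    "compound_call_pairs",
    "on_target_signature",
    "sirna_signature",
    "off_target_signature",
    "off_target_member",
    "classify_profiles",
    "counter_therapeutic_count",
    "cluster_treatments",
    "linkage_to_newick",
]

log = get_logger(__name__)

PROFILE_CLASSES = (
    "bipolar",
    "common",
    "pure_off_target",
    "additive",
    "inverse",
    "pure_on_target",
    "unclassified",
)


@dataclass(frozen=True)
class RegulationCallPair:
    gene_id: str
    tgf_call: str
    wotgf_call: str
    concentration_uM: float
    time_h: float


@dataclass
class SignatureSet:
    """A named signed gene set; members maps gene_id -> 'up' | 'down'."""

    name: str
    role: str  # on_target | off_target | treatment
    time_h: float | None
    members: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {d for d in self.members.values()} - {"up", "down"}
        if bad:
            raise ValueError(f"signature {self.name!r}: invalid directions {bad}")

    @property
    def genes(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.members.items()), columns=["gene_id", "direction"]
        ).set_index("gene_id")


# ---------------------------------------------------------------------------
# Contrast helpers


def stimulation_contrast(
    study: ExpressionStudy,
    time_h: float,
    config: AnalysisConfig,
    *,
    vehicle: str = "dmso",
    moderation: bool = True,
) -> pd.DataFrame:
    """Stimulated vehicle vs unstimulated vehicle at one time (filter 1)."""
    idx_a = study.select(modulator="none", vehicle=vehicle, stimulated=True, time_h=time_h)
    idx_b = study.select(modulator="none", vehicle=vehicle, stimulated=False, time_h=time_h)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(f"stimulation contrast at t={time_h}: vehicle arms missing")
    return contrast_from_groups(
        study.values[:, idx_a],
        study.values[:, idx_b],
        study.genes,
        moderation=moderation,
        alpha=config.alpha,
        lr_min=config.on_target_lr_min,
        name=f"TGF_vs_unstim_t{time_h:g}",
    )


def arm_contrast(
    study: ExpressionStudy,
    compound: str,
    concentration: float,
    time_h: float,
    *,
    stimulated: bool,
    config: AnalysisConfig,
    lr_min: float | None = None,
    moderation: bool = True,
) -> pd.DataFrame:
    """Compound at one dose vs DMSO vehicle, within one stimulation arm."""
    idx_a = study.select(
        modulator="nce",
        compound_id=compound,
        concentration_uM=concentration,
        time_h=time_h,
        stimulated=stimulated,
    )
    idx_b = study.select(
        modulator="none", vehicle="dmso", time_h=time_h, stimulated=stimulated
    )
    tag = "tgf" if stimulated else "wotgf"
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError(
            f"{compound} {concentration:g} uM t={time_h:g} ({tag}): missing samples"
        )
    return contrast_from_groups(
        study.values[:, idx_a],
        study.values[:, idx_b],
        study.genes,
        moderation=moderation,
        alpha=config.alpha,
        lr_min=config.lr_min if lr_min is None else lr_min,
        name=f"{compound}_{concentration:g}uM_{tag}_t{time_h:g}",
    )


def compound_call_pairs(
    study: ExpressionStudy,
    compound: str,
    config: AnalysisConfig,
    *,
    times: Sequence[float] | None = None,
    moderation: bool = True,
) -> list[RegulationCallPair]:
    """Regulation call pairs (tgf vs wotgf arm) at the read-out concentrations."""
    times = study.times() if times is None else list(times)
    pairs: list[RegulationCallPair] = []
    for t in times:
        for conc in config.offtarget_concentrations_uM:
            tgf = arm_contrast(
                study, compound, conc, t, stimulated=True, config=config, moderation=moderation
            )
            wotgf = arm_contrast(
                study, compound, conc, t, stimulated=False, config=config, moderation=moderation
            )
            for gene in study.genes:
                pairs.append(
                    RegulationCallPair(
                        gene_id=gene,
                        tgf_call=tgf.at[gene, "call"],
                        wotgf_call=wotgf.at[gene, "call"],
                        concentration_uM=conc,
                        time_h=t,
                    )
                )
    return pairs


# ---------------------------------------------------------------------------
# On-target signature (three sequential filters)


def _dose_series(study: ExpressionStudy, compound: str, time_h: float) -> list[float]:
    concs = sorted(
        {
            s.concentration_uM
            for s in study.samples
            if s.modulator == "nce"
            and s.compound_id == compound
            and s.stimulated
            and s.time_h == time_h
        }
    )
    if len(concs) < 3:
        raise ValueError(
            f"compound {compound!r} has no usable dose series at t={time_h:g} "
            f"({len(concs)} concentrations)"
        )
    return concs


def _replicate_lrs(
    study: ExpressionStudy, compound: str, time_h: float, concs: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate log2 ratios to the stimulated vehicle mean, dose-labelled."""
    idx_v = study.select(modulator="none", vehicle="dmso", stimulated=True, time_h=time_h)
    vehicle_mean = study.values[:, idx_v].mean(axis=1, keepdims=True)
    blocks, labels = [], []
    for level, conc in enumerate(concs):
        idx = study.select(
            modulator="nce",
            compound_id=compound,
            concentration_uM=conc,
            stimulated=True,
            time_h=time_h,
        )
        blocks.append(study.values[:, idx] - vehicle_mean)
        labels.append(np.full(len(idx), level))
    return np.concatenate(blocks, axis=1), np.concatenate(labels)


def on_target_signature(
    study: ExpressionStudy,
    compounds: Sequence[str],
    time_h: float,
    config: AnalysisConfig,
    *,
    moderation: bool = True,
    rng: np.random.Generator | None = None,
) -> SignatureSet:
    """Pathway signature at one time point, pooled over compounds.

    Filter 1 keeps stimulation-responsive genes, filter 2 keeps those touched
    by >= 1 concentration of the compound under stimulation, filter 3 keeps
    those with a significant dose trend in the replicate-level log2 ratios.
    The returned set carries ``per_compound`` and ``filter_counts``
    attributes for logging/inspection.
    """
    rng = config.rng() if rng is None else rng
    f1 = stimulation_contrast(study, time_h, config, moderation=moderation)
    f1_genes = f1.index[f1["call"] != "none"]
    direction = f1.loc[f1_genes, "call"]
    gene_pos = study.gene_index()

    members: dict[str, str] = {}
    per_compound: dict[str, set[str]] = {}
    counts: dict[str, dict[str, int]] = {}
    for compound in compounds:
        concs = _dose_series(study, compound, time_h)
        sig_any = pd.Series(False, index=f1_genes)
        for conc in concs:
            table = arm_contrast(
                study, compound, conc, time_h, stimulated=True, config=config,
                moderation=moderation,
            )
            sig_any |= table.loc[f1_genes, "p_adj"] < config.alpha
        f2_genes = list(sig_any.index[sig_any])
        f3_genes: list[str] = []
        if f2_genes:
            lrs, labels = _replicate_lrs(study, compound, time_h, concs)
            rows = [gene_pos[g] for g in f2_genes]
            out = trend_test_batch(
                lrs[rows], labels, B=config.permutations_B, rng=rng
            )
            f3_genes = [g for g, p in zip(f2_genes, out["p_perm"]) if p < config.alpha]
        per_compound[compound] = set(f3_genes)
        counts[compound] = {
            "filter1": len(f1_genes), "filter2": len(f2_genes), "filter3": len(f3_genes),
        }
        for g in f3_genes:
            members[g] = direction.at[g]
        log.info(
            "on-target t=%g %s: filter1=%d filter2=%d filter3=%d",
            time_h, compound, len(f1_genes), len(f2_genes), len(f3_genes),
        )
    sig = SignatureSet(
        name=f"on_target_t{time_h:g}", role="on_target", time_h=time_h, members=members
    )
    sig.per_compound = per_compound  # type: ignore[attr-defined]
    sig.filter_counts = counts  # type: ignore[attr-defined]
    log.info("on-target t=%g pooled signature: %d genes", time_h, len(sig))
    return sig


def sirna_signature(
    study: ExpressionStudy,
    time_h: float,
    config: AnalysisConfig,
    *,
    active_id: str = "siRNA_A1",
    control_id: str = "siRNA_ctrl",
    moderation: bool = True,
) -> SignatureSet:
    """Knockdown signature: filter-1 genes hit by the active but not the
    control siRNA (each vs the transfection vehicle, adjusted p)."""

    def sirna_table(sirna: str) -> pd.DataFrame:
        idx_a = study.select(
            modulator="sirna", compound_id=sirna, stimulated=True, time_h=time_h
        )
        idx_b = study.select(
            modulator="none", vehicle="transfection", stimulated=True, time_h=time_h
        )
        if len(idx_a) < 2 or len(idx_b) < 2:
            raise ValueError(f"siRNA arm {sirna!r} or its vehicle missing at t={time_h:g}")
        return contrast_from_groups(
            study.values[:, idx_a], study.values[:, idx_b], study.genes,
            moderation=moderation, alpha=config.alpha, lr_min=config.on_target_lr_min,
            name=f"{sirna}_t{time_h:g}",
        )

    f1 = stimulation_contrast(study, time_h, config, moderation=moderation)
    f1_genes = f1.index[f1["call"] != "none"]
    active = sirna_table(active_id)
    control = sirna_table(control_id)
    keep = f1_genes[
        (active.loc[f1_genes, "p_adj"] < config.alpha).to_numpy()
        & (control.loc[f1_genes, "call"] == "none").to_numpy()
    ]
    members = {g: f1.at[g, "call"] for g in keep}
    log.info(
        "siRNA signature t=%g: filter1=%d active-hit=%d", time_h, len(f1_genes), len(members)
    )
    return SignatureSet(
        name=f"sirna_t{time_h:g}", role="on_target", time_h=time_h, members=members
    )


# ---------------------------------------------------------------------------
# Off-target signature


def off_target_member(tgf_call: str, wotgf_call: str) -> bool:
    """Boolean membership rule: significant in BOTH arms, any sign combination.

    (tgf_up & wotgf_up) | (tgf_down & wotgf_down) |
    (tgf_up & wotgf_down) | (tgf_down & wotgf_up)
    """
    return (
        (tgf_call == "up" and wotgf_call == "up")
        or (tgf_call == "down" and wotgf_call == "down")
        or (tgf_call == "up" and wotgf_call == "down")
        or (tgf_call == "down" and wotgf_call == "up")
    )


@dataclass
class OffTargetResult:
    compound: str
    per_time: dict[float, SignatureSet]
    pooled: SignatureSet


def off_target_signature(
    pairs: Iterable[RegulationCallPair],
    compound: str,
    config: AnalysisConfig,
) -> OffTargetResult:
    """Off-target signature of one compound from tgf/wotgf call pairs.

    Membership requires both arms significant at the SAME concentration and
    time; the recorded direction is the unstimulated-arm call (target-
    independent regulation).  Per-time sets are retained and pooled.
    """
    per_time: dict[float, dict[str, str]] = {}
    pooled: dict[str, str] = {}
    for pair in pairs:
        if off_target_member(pair.tgf_call, pair.wotgf_call):
            per_time.setdefault(pair.time_h, {}).setdefault(pair.gene_id, pair.wotgf_call)
            pooled.setdefault(pair.gene_id, pair.wotgf_call)
    per_time_sets = {
        t: SignatureSet(
            name=f"off_target_{compound}_t{t:g}", role="off_target", time_h=t, members=m
        )
        for t, m in sorted(per_time.items())
    }
    pooled_set = SignatureSet(
        name=f"off_target_{compound}", role="off_target", time_h=None, members=pooled
    )
    log.info(
        "off-target %s: %s pooled=%d",
        compound, {t: len(s) for t, s in per_time_sets.items()}, len(pooled_set),
    )
    return OffTargetResult(compound=compound, per_time=per_time_sets, pooled=pooled_set)


# ---------------------------------------------------------------------------
# Six-class response profiles


def _sign(call: str) -> int:
    return {"up": 1, "down": -1}.get(call, 0)


def classify_profiles(
    study: ExpressionStudy,
    time_h: float,
    config: AnalysisConfig,
    *,
    compounds: Sequence[str] | None = None,
    on_target: SignatureSet | None = None,
    moderation: bool = True,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign one of the six response-profile classes per (gene, compound).

    Decision tree, first match wins:
      1. bipolar          opposite-signed significant calls at the low vs high
                          read-out concentration in either arm
      2. common           same-direction significant unstimulated-arm calls for
                          ALL compounds at both concentrations and no dose
                          trend in the stimulated-arm log2 ratios
      3. pure_off_target  no stimulation response (not in filter 1) but
                          same-direction significant calls in both arms
      4. additive         stimulation-responsive and the compound alone pushes
                          the gene in the same direction as the stimulus
      5. inverse          stimulation-responsive and the compound alone pushes
                          the gene the other way
      6. pure_on_target   in the on-target signature, no unstimulated-arm call
    Returns a genes x compounds DataFrame of class labels for one time point.
    """
    rng = config.rng() if rng is None else rng
    compounds = study.compounds() if compounds is None else list(compounds)
    concs = config.offtarget_concentrations_uM
    low, high = concs[0], concs[-1]
    if on_target is None:
        on_target = on_target_signature(
            study, compounds, time_h, config, moderation=moderation, rng=rng
        )
    f1 = stimulation_contrast(study, time_h, config, moderation=moderation)
    f1_call = f1["call"]

    calls: dict[tuple[str, float, str], pd.Series] = {}
    for compound in compounds:
        for conc in concs:
            for arm, stim in (("tgf", True), ("wotgf", False)):
                table = arm_contrast(
                    study, compound, conc, time_h, stimulated=stim, config=config,
                    moderation=moderation,
                )
                calls[(compound, conc, arm)] = table["call"]

    # "common" candidates: same-direction significant wotgf calls for every
    # compound at both concentrations
    wotgf_signs = np.stack(
        [
            np.array([_sign(c) for c in calls[(comp, conc, "wotgf")]])
            for comp in compounds
            for conc in concs
        ]
    )
    all_same = (np.abs(wotgf_signs).min(axis=0) > 0) & (
        np.abs(wotgf_signs.sum(axis=0)) == wotgf_signs.shape[0]
    )
    common_candidates = [g for g, flag in zip(study.genes, all_same) if flag]

    # dose-trend p for common candidates, per compound (stimulated-arm LRs)
    trend_p: dict[str, pd.Series] = {}
    gene_pos = study.gene_index()
    if common_candidates:
        for compound in compounds:
            series = _dose_series(study, compound, time_h)
            lrs, labels = _replicate_lrs(study, compound, time_h, series)
            rows = [gene_pos[g] for g in common_candidates]
            out = trend_test_batch(lrs[rows], labels, B=config.permutations_B, rng=rng)
            trend_p[compound] = pd.Series(out["p_perm"], index=common_candidates)

    result = {}
    on_genes = on_target.genes
    for compound in compounds:
        tgf_low = calls[(compound, low, "tgf")]
        tgf_high = calls[(compound, high, "tgf")]
        wotgf_low = calls[(compound, low, "wotgf")]
        wotgf_high = calls[(compound, high, "wotgf")]
        labels = []
        for g in study.genes:
            s_f1 = _sign(f1_call.at[g])
            s_tl, s_th = _sign(tgf_low.at[g]), _sign(tgf_high.at[g])
            s_wl, s_wh = _sign(wotgf_low.at[g]), _sign(wotgf_high.at[g])
            in_f1 = s_f1 != 0
            if (s_tl * s_th == -1) or (s_wl * s_wh == -1):
                labels.append("bipolar")
            elif (
                g in trend_p.get(compound, {})
                and trend_p[compound].at[g] >= config.alpha
            ):
                labels.append("common")
            elif not in_f1 and any(
                _sign(calls[(compound, conc, "tgf")].at[g]) != 0
                and _sign(calls[(compound, conc, "tgf")].at[g])
                == _sign(calls[(compound, conc, "wotgf")].at[g])
                for conc in concs
            ):
                labels.append("pure_off_target")
            elif in_f1 and any(s == s_f1 for s in (s_wl, s_wh) if s != 0):
                labels.append("additive")
            elif in_f1 and any(s == -s_f1 for s in (s_wl, s_wh) if s != 0):
                labels.append("inverse")
            elif g in on_genes and s_wl == 0 and s_wh == 0:
                labels.append("pure_on_target")
            else:
                labels.append("unclassified")
        result[compound] = labels
    frame = pd.DataFrame(result, index=pd.Index(study.genes, name="gene_id"))
    for compound in compounds:
        tally = frame[compound].value_counts().to_dict()
        log.info("profiles t=%g %s: %s", time_h, compound, tally)
    return frame


def counter_therapeutic_count(
    on_target: SignatureSet,
    wotgf_calls: Mapping[str, pd.Series] | Sequence[pd.Series],
) -> int:
    """Number of on-target genes a compound pushes towards the stimulated state.

    A gene counts when its compound-alone (unstimulated arm) call at any
    supplied concentration/time matches the direction the stimulus drives it —
    i.e. the compound's target-independent action opposes the intended
    reversal.  Convention: direction taken from the on-target signature,
    membership pooled over the supplied call tables.
    """
    tables = list(wotgf_calls.values()) if isinstance(wotgf_calls, Mapping) else list(wotgf_calls)
    count = 0
    for gene, direction in on_target.members.items():
        for table in tables:
            if gene in table.index and table.at[gene] == direction:
                count += 1
                break
    log.info(
        "counter-therapeutic count: %d of %d on-target genes "
        "(wotgf call equals stimulation direction at >=1 condition)",
        count, len(on_target),
    )
    return count


# ---------------------------------------------------------------------------
# Treatment-signature clustering


@dataclass
class TreatmentClustering:
    labels: list[str]
    feature_genes: list[str]
    matrix: pd.DataFrame  # profiles x genes, signed LRs
    linkage: np.ndarray
    leaf_order: list[str]
    newick: str

    def merge_heights(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage, columns=["child_a", "child_b", "height", "n_leaves"]
        )


def cluster_treatments(profiles: Mapping[str, pd.DataFrame]) -> TreatmentClustering:
    """Cluster treatment profiles (compound x concentration) at one time.

    ``profiles`` maps a label to a contrast table with ``lr`` and ``call``
    columns.  Features are the signed LRs over the union of genes significant
    in >= 1 profile; distance manhattan, linkage complete.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 treatment profiles to cluster")
    labels = list(profiles)
    union: list[str] = []
    seen = set()
    for label in labels:
        table = profiles[label]
        for g in table.index[table["call"] != "none"]:
            if g not in seen:
                seen.add(g)
                union.append(g)
    if not union:
        raise ValueError("no gene is significant in any profile; nothing to cluster")
    matrix = pd.DataFrame(
        {label: profiles[label].loc[union, "lr"] for label in labels}
    ).T
    z = hierarchy.linkage(pdist(matrix.to_numpy(), metric="cityblock"), method="complete")
    order = [labels[i] for i in hierarchy.leaves_list(z)]
    newick = linkage_to_newick(z, labels)
    log.info(
        "cluster_treatments: %d profiles over %d significant genes", len(labels), len(union)
    )
    return TreatmentClustering(
        labels=labels, feature_genes=union, matrix=matrix, linkage=z,
        leaf_order=order, newick=newick,
    )


def linkage_to_newick(z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(z)

    def walk(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"
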