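"""Synthetic phenocopy studies with planted ground truth.

The generator emulates a lead-optimization expression-profiling campaign on a
TGF-beta reporter cell system: seven kinase-inhibitor compounds (five of one
chemotype, two of another) at seven concentrations spanning 3.2 nM - 50 uM,
three time points, biological triplicates, stimulated (+TGF-beta) arms across
the full dose series, unstimulated arms only at the two off-target read-out
concentrations, DMSO vehicle controls, and siRNA / control-siRNA /
transfection-vehicle arms.

Each gene is planted into one of seven response classes:

  null            no effect anywhere
  pure_on_target  responds to stimulation; response reversed dose-dependently
                  by every compound through target inhibition
  pure_off_target no stimulation response; dose-dependent compound effect in
                  both arms for the compounds that hit it
  additive        stimulation response plus a same-signed off-target effect
  inverse         stimulation response plus an opposite-signed off-target effect
  bipolar         off-target effect that flips sign between low and high dose
                  (a toxicity-like profile)
  common          identical dose-independent shift under every compound

The mean model for gene g in sample s is

  baseline_g + stimulated * tgf_lr_g * (1 - pathway_inhibition)
             + off_effect_g(compound, concentration)

with pathway_inhibition = c / (c + IC50_compound) under a compound at dose c
(Hill exponent 1 by default), a configurable fraction under the active siRNA,
and 0 otherwise.  Off-target effects follow a per-gene Hill curve
c^h / (c^h + ic50_g^h), except bipolar (sign flip at a dose threshold) and
common (constant).  Noise is independent Gaussian on the log2 scale with a
gene-wise sd drawn from a Gamma distribution.

A companion generator plants hit kinases into a single-point selectivity panel
and builds a kinase-to-surrogate-marker map, so the panel selection rule and
the marker overlay can be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ExpressionStudy, GeneSet, SampleRecord, get_logger

__all__ = [
    "CompoundSpec",
    "GeneTruth",
    "SimConfig",
    "generate_study",
    "generate_kinase_panel",
    "generate_gene_sets",
    "expected_profiles",
    "default_compounds",
    "SIRNA_ACTIVE",
    "SIRNA_CONTROL",
]

log = get_logger(__name__)

SIRNA_ACTIVE = "siRNA_A1"
SIRNA_CONTROL = "siRNA_ctrl"

CLASSES = ("null", "pure_on_target", "pure_off_target", "additive", "inverse", "bipolar", "common")


@dataclass(frozen=True)
class CompoundSpec:
    compound_id: str
    cellular_ic50_uM: float
    chemotype: str
    offtarget_weight: float = 1.0


def default_compounds() -> list[CompoundSpec]:
    """Seven inhibitors: five indolinones, two pyridopyrimidinones.

    Cellular potencies span the tens-of-nM to low-uM range typical for
    advanced leads vs weaker competitor compounds; off-target weights make
    the first indolinone and both pyridopyrimidinones promiscuous, mirroring
    a campaign where scaffold decoration drives selectivity.
    """
    return [
        CompoundSpec("BI1", 0.050, "indolinone", 8.0),
        CompoundSpec("BI2", 0.040, "indolinone", 0.95),
        CompoundSpec("BI3", 0.019, "indolinone", 0.85),
        CompoundSpec("BI4", 0.060, "indolinone", 0.97),
        CompoundSpec("BI5", 0.080, "indolinone", 1.0),
        CompoundSpec("Ex1", 0.500, "pyridopyrimidinone", 3.8),
        CompoundSpec("Ex2", 1.500, "pyridopyrimidinone", 3.7),
    ]


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    klass: str
    tgf_lr: float
    off_lr: float
    ic50_uM: float
    hill: float
    affected_compounds: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown gene class {self.klass!r}")
        if self.klass == "null" and (self.tgf_lr != 0 or self.off_lr != 0):
            raise ValueError("null genes must have zero effects")
        if self.klass == "pure_on_target" and self.off_lr != 0:
            raise ValueError("pure_on_target genes must have off_lr = 0")
        if self.klass == "pure_off_target" and self.tgf_lr != 0:
            raise ValueError("pure_off_target genes must have tgf_lr = 0")


@dataclass
class SimConfig:
    """Study layout and effect-size conditions for the generator."""

    n_genes: int = 5000
    class_proportions: dict = field(
        default_factory=lambda: {
            "null": 0.80,
            "pure_on_target": 0.08,
            "pure_off_target": 0.04,
            "additive": 0.02,
            "inverse": 0.02,
            "bipolar": 0.02,
            "common": 0.02,
        }
    )
    compounds: list[CompoundSpec] = field(default_factory=default_compounds)
    concentrations_uM: tuple[float, ...] = (0.0032, 0.016, 0.08, 0.4, 2.0, 10.0, 50.0)
    times_h: tuple[float, ...] = (2.0, 4.0, 12.0)
    replicates: int = 3
    offtarget_concentrations_uM: tuple[float, ...] = (0.08, 2.0)
    # gene-wise noise sd ~ Gamma(shape, scale); defaults give mean 0.35, sd 0.05
    noise_sd_shape: float = 49.0
    noise_sd_scale: float = 0.35 / 49.0
    effect_lr_range: tuple[float, float] = (1.5, 3.0)
    gene_ic50_range_uM: tuple[float, float] = (0.02, 0.5)
    hill: float = 1.0
    bipolar_threshold_uM: float = 0.4
    sirna_inhibition: float = 0.6
    chemotype_share_prob: float = 0.2
    baseline_range: tuple[float, float] = (6.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes {sorted(unknown)}")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if not set(self.offtarget_concentrations_uM) <= set(self.concentrations_uM):
            raise ValueError("off-target concentrations must be part of the dose series")


def _hill(conc: float, ic50: float, hill: float) -> float:
    if conc <= 0:
        return 0.0
    return conc**hill / (conc**hill + ic50**hill)


def _draw_truth(config: SimConfig, rng: np.random.Generator) -> list[GeneTruth]:
    classes = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in classes])
    draw = rng.choice(len(classes), size=config.n_genes, p=probs)
    lo, hi = config.effect_lr_range
    ic_lo, ic_hi = config.gene_ic50_range_uM
    weights = np.array([c.offtarget_weight for c in config.compounds], dtype=float)
    weights = weights / weights.sum()
    chemotypes: dict[str, list[str]] = {}
    for c in config.compounds:
        chemotypes.setdefault(c.chemotype, []).append(c.compound_id)
    chem_of = {c.compound_id: c.chemotype for c in config.compounds}
    all_ids = tuple(c.compound_id for c in config.compounds)

    truths = []
    width = len(str(config.n_genes))
    for i, ki in enumerate(draw):
        klass = classes[ki]
        gene_id = f"G{i + 1:0{width}d}"
        tgf_lr = off_lr = 0.0
        affected: tuple[str, ...] = ()
        ic50 = float(np.exp(rng.uniform(np.log(ic_lo), np.log(ic_hi))))
        if klass in ("pure_on_target", "additive", "inverse"):
            tgf_lr = float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
        if klass in ("pure_off_target", "additive", "inverse", "bipolar", "common"):
            mag = float(rng.uniform(lo, hi))
            if klass == "additive":
                off_lr = mag * np.sign(tgf_lr)
            elif klass == "inverse":
                off_lr = -mag * np.sign(tgf_lr)
            else:
                off_lr = mag * float(rng.choice([-1.0, 1.0]))
            if klass == "common":
                affected = all_ids
            else:
                pick = config.compounds[rng.choice(len(config.compounds), p=weights)]
                if rng.random() < config.chemotype_share_prob:
                    affected = tuple(chemotypes[chem_of[pick.compound_id]])
                else:
                    affected = (pick.compound_id,)
        truths.append(
            GeneTruth(
                gene_id=gene_id,
                klass=klass,
                tgf_lr=tgf_lr,
                off_lr=off_lr,
                ic50_uM=ic50,
                hill=config.hill,
                affected_compounds=affected,
            )
        )
    return truths


def _build_design(config: SimConfig) -> list[SampleRecord]:
    samples: list[SampleRecord] = []

    def add(**kw) -> None:
        samples.append(SampleRecord(**kw))

    for t in config.times_h:
        for stim in (True, False):
            tag = "tgf" if stim else "wotgf"
            for r in range(1, config.replicates + 1):
                add(
                    sample_id=f"DMSO_{tag}_t{t:g}_r{r}",
                    modulator="none",
                    compound_id=None,
                    concentration_uM=None,
                    time_h=t,
                    stimulated=stim,
                    vehicle="dmso",
                    replicate=r,
                )
            for comp in config.compounds:
                concs = (
                    config.concentrations_uM if stim else config.offtarget_concentrations_uM
                )
                for c in concs:
                    for r in range(1, config.replicates + 1):
                        add(
                            sample_id=f"{comp.compound_id}_{c:g}uM_{tag}_t{t:g}_r{r}",
                            modulator="nce",
                            compound_id=comp.compound_id,
                            concentration_uM=c,
                            time_h=t,
                            stimulated=stim,
                            vehicle="dmso",
                            replicate=r,
                        )
        # siRNA arms are stimulated only: the question they answer is whether
        # knocking down the receptor removes the stimulation response
        for r in range(1, config.replicates + 1):
            add(
                sample_id=f"MOCK_tgf_t{t:g}_r{r}",
                modulator="none",
                compound_id=None,
                concentration_uM=None,
                time_h=t,
                stimulated=True,
                vehicle="transfection",
                replicate=r,
            )
        for sirna in (SIRNA_ACTIVE, SIRNA_CONTROL):
            for r in range(1, config.replicates + 1):
                add(
                    sample_id=f"{sirna}_tgf_t{t:g}_r{r}",
                    modulator="sirna",
                    compound_id=sirna,
                    concentration_uM=None,
                    time_h=t,
                    stimulated=True,
                    vehicle="transfection",
                    replicate=r,
                )
    return samples


def _mean_value(truth: GeneTruth, sample: SampleRecord, config: SimConfig, baseline: float,
                ic50_by_compound: Mapping[str, float]) -> float:
    value = baseline
    inhibition = 0.0
    if sample.modulator == "nce":
        inhibition = _hill(sample.concentration_uM, ic50_by_compound[sample.compound_id],
                           config.hill)
    elif sample.modulator == "sirna" and sample.compound_id == SIRNA_ACTIVE:
        inhibition = config.sirna_inhibition
    if sample.stimulated and truth.tgf_lr != 0.0:
        value += truth.tgf_lr * (1.0 - inhibition)
    if (
        sample.modulator == "nce"
        and truth.off_lr != 0.0
        and sample.compound_id in truth.affected_compounds
    ):
        c = sample.concentration_uM
        if truth.klass == "common":
            value += truth.off_lr
        elif truth.klass == "bipolar":
            value += truth.off_lr if c < config.bipolar_threshold_uM else -truth.off_lr
        else:
            value += truth.off_lr * _hill(c, truth.ic50_uM, truth.hill)
    return value


def generate_study(config: SimConfig) -> tuple[ExpressionStudy, list[GeneTruth]]:
    """Simulate an expression study; deterministic under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    truths = _draw_truth(config, rng)
    samples = _build_design(config)
    baselines = rng.uniform(*config.baseline_range, size=config.n_genes)
    if config.noise_sd_scale > 0:
        noise_sd = rng.gamma(config.noise_sd_shape, config.noise_sd_scale, size=config.n_genes)
    else:
        noise_sd = np.zeros(config.n_genes)

    ic50_by_compound = {c.compound_id: c.cellular_ic50_uM for c in config.compounds}
    means = np.empty((config.n_genes, len(samples)))
    for j, sample in enumerate(samples):
        for i, truth in enumerate(truths):
            means[i, j] = _mean_value(truth, sample, config, baselines[i], ic50_by_compound)
    if noise_sd.any():
        values = means + rng.normal(size=means.shape) * noise_sd[:, None]
    else:
        values = means
    study = ExpressionStudy(
        genes=[t.gene_id for t in truths], samples=samples, values=values
    )
    log.info(
        "generate_study: %d genes x %d samples, %d compounds, seed=%d",
        study.n_genes, study.n_samples, len(config.compounds), config.seed,
    )
    return study, truths


def truth_frame(truths: Sequence[GeneTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in truths],
            "klass": [t.klass for t in truths],
            "tgf_lr": [t.tgf_lr for t in truths],
            "off_lr": [t.off_lr for t in truths],
            "ic50_uM": [t.ic50_uM for t in truths],
            "hill": [t.hill for t in truths],
            "affected_compounds": [";".join(t.affected_compounds) for t in truths],
        }
    ).set_index("gene_id")


def expected_profiles(
    truths: Sequence[GeneTruth], compounds: Sequence[str]
) -> pd.DataFrame:
    """Expected noise-free profile class per (gene, compound).

    A compound that does not hit a gene's off-target mechanism sees only the
    gene's stimulation response: such (gene, compound) pairs are expected
    pure_on_target when the gene responds to stimulation, else unclassified.
    """
    rows = {}
    for t in truths:
        row = {}
        for c in compounds:
            if t.klass == "null":
                row[c] = "unclassified"
            elif t.klass == "pure_on_target":
                row[c] = "pure_on_target"
            elif c in t.affected_compounds:
                row[c] = t.klass
            else:
                row[c] = "pure_on_target" if t.tgf_lr != 0 else "unclassified"
        rows[t.gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(compounds)]


# ---------------------------------------------------------------------------
# Kinase panel + surrogate-marker map


def generate_kinase_panel(
    n_kinases: int,
    compounds: Sequence[str],
    planted_hits: Mapping[str, Sequence[str] | int],
    seed: int = 0,
    *,
    markers_per_kinase: tuple[int, int] = (0, 8),
    redundancy: float = 0.0,
    marker_pool: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, frozenset[str]], dict[str, frozenset[str]]]:
    """Single-point inhibition panel with planted hit kinases.

    planted_hits maps compound -> kinase IDs (or a count to draw at random).
    Hits receive inhibition >= 90% at 2 uM and >= 50% at 200 nM; non-hits fail
    at least one threshold (with a safety margin, so the rule's boundary is
    exercised only deliberately).  The surrogate map assigns 0..k markers per
    kinase; with redundancy > 0 markers may be shared between kinases,
    with redundancy = 0 every marker belongs to exactly one kinase.

    Returns (panel table, surrogate map, truth map compound -> hit kinases).
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_kinases))
    kinases = [f"K{i + 1:0{width}d}" for i in range(n_kinases)]
    truth: dict[str, frozenset[str]] = {}
    rows = []
    for compound in compounds:
        wanted = planted_hits.get(compound, ())
        if isinstance(wanted, (int, np.integer)):
            if wanted > n_kinases:
                raise ValueError(f"{compound}: cannot plant {wanted} hits among {n_kinases} kinases")
            hits = set(rng.choice(kinases, size=int(wanted), replace=False))
        else:
            hits = set(wanted)
            if not hits <= set(kinases):
                raise ValueError(f"{compound}: planted hits outside the kinase list")
        truth[compound] = frozenset(hits)
        for kin in kinases:
            if kin in hits:
                i2, i02 = rng.uniform(90.0, 110.0), rng.uniform(50.0, 105.0)
            else:
                mode = rng.random()
                if mode < 1 / 3:  # potent at 2 uM but washed out at 200 nM
                    i2, i02 = rng.uniform(90.0, 110.0), rng.uniform(-50.0, 45.0)
                elif mode < 2 / 3:  # weak at both
                    i2, i02 = rng.uniform(-50.0, 85.0), rng.uniform(-50.0, 45.0)
                else:  # odd but legal: stronger at the lower concentration
                    i2, i02 = rng.uniform(-50.0, 85.0), rng.uniform(50.0, 105.0)
            rows.append((kin, compound, round(float(i2), 1), round(float(i02), 1)))
    panel = pd.DataFrame(
        rows, columns=["kinase_id", "compound_id", "inhibition_2uM", "inhibition_200nM"]
    )

    lo, hi = markers_per_kinase
    surrogate: dict[str, frozenset[str]] = {}
    used: list[str] = []
    counter = 0
    for kin in kinases:
        n_mark = int(rng.integers(lo, hi + 1))
        members: set[str] = set()
        while len(members) < n_mark:
            if used and rng.random() < redundancy:
                members.add(used[int(rng.integers(len(used)))])
            elif marker_pool is not None:
                members.add(marker_pool[int(rng.integers(len(marker_pool)))])
            else:
                counter += 1
                members.add(f"M{counter:05d}")
        surrogate[kin] = frozenset(members)
        used.extend(members)
    return panel, surrogate, truth


def generate_gene_sets(
    truths: Sequence[GeneTruth],
    compounds: Sequence[CompoundSpec],
    *,
    n_random_sets: int = 30,
    set_size: int = 40,
    seed: int = 0,
) -> list[GeneSet]:
    """Gene-set collection with structure tied to the planted truth.

    Builds one pathway-like set per chemotype enriched in that chemotype's
    off-target genes (the toxicity/inflammation-tagged sets for the scorecard
    narrative), one set from on-target genes, and random background sets.
    """
    rng = np.random.default_rng(seed)
    all_genes = [t.gene_id for t in truths]
    by_chemo: dict[str, list[str]] = {}
    chem_of = {c.compound_id: c.chemotype for c in compounds}
    for t in truths:
        if t.off_lr != 0 and t.klass != "common":
            for cid in t.affected_compounds:
                by_chemo.setdefault(chem_of[cid], []).append(t.gene_id)
    sets: list[GeneSet] = []
    for chemo, genes in sorted(by_chemo.items()):
        genes = sorted(set(genes))
        half = len(genes) // 2
        for tag, part in (("TOX", genes[:half]), ("INFLAM", genes[half:])):
            core = list(rng.choice(part, size=min(len(part), set_size * 3 // 4), replace=False))
            pad = [g for g in rng.choice(all_genes, size=set_size, replace=False) if g not in core]
            members = tuple(core + pad[: max(0, set_size - len(core))])
            sets.append(
                GeneSet(f"{tag}_{chemo.upper()}", f"off-target genes of {chemo}", members)
            )
    on_genes = sorted(t.gene_id for t in truths if t.klass == "pure_on_target")
    if on_genes:
        core = list(rng.choice(on_genes, size=min(len(on_genes), set_size), replace=False))
        sets.append(GeneSet("PATHWAY_TGFB", "stimulation-responsive genes", tuple(core)))
    for i in range(n_random_sets):
        members = tuple(rng.choice(all_genes, size=set_size, replace=False))
        sets.append(GeneSet(f"RANDOM_{i + 1:02d}", "background set", members))
    return sets
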