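# phenocopy

Qualifying kinase-inhibitor drug candidates by the transcriptional
*phenocopies* they induce: a compound that inhibits its target should
reproduce the expression state of a genetic knockdown of that target, and
everything it does beyond that is an off-target liability.  This package
implements that idea as a reusable analysis pipeline for lead optimization:
from a log2 expression matrix over a compound × dose × time × ±stimulus
design it derives on-target and off-target gene signatures, classifies
per-gene response profiles, enriches signatures against gene-set
collections, overlays biochemical kinase-panel selectivity with surrogate
markers, and ranks the compounds on a multi-criterion scorecard.

The motivating setting is a TGF-β receptor I kinase program: cells are
stimulated with TGF-β and treated with candidate inhibitors across a dose
series (3.2 nM – 50 µM), so each gene's behaviour separates into a pathway
component (reversed dose-dependently by target inhibition) and a
compound-specific component (present with and without the stimulus).

## The statistics at the core

**Moderated two-group contrasts.** Every comparison is pairwise on log2
data: LR = mean(A) − mean(B), with the pooled per-gene variance s²_g (d_g
df) shrunk through the empirical-Bayes hierarchy
s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), the prior (d₀, s₀²) moment-matched
from log s²_g across genes; t = LR/(s̃_g√(1/n_A+1/n_B)) with d₀+d_g df.
P-values are BH-adjusted per contrast; calls are `up`/`down` when
p_adj < α (0.01) and |LR| clears the threshold (1.0 for off-target rules).

**Isotonic dose-trend test.** A gene responds dose-dependently when the
monotone least-squares fit across ordered dose groups explains its
variance: E² = (SS₀ − SS_iso)/SS₀, maximised over both directions, with a
permutation null on the sample-to-dose assignment,
p = (1 + #{E²_perm ≥ E²_obs})/(B+1).

**On-target signature** (per time point): genes significant for stimulated
vs unstimulated vehicle → of those, significant for ≥ 1 compound
concentration under stimulation → of those, significant dose trend in the
replicate-level log2 ratios; survivors pooled over compounds.  An siRNA
variant replaces the dose series with an active-vs-control knockdown pair.

**Off-target signature** (per compound): a gene qualifies iff at some
read-out concentration (0.08 or 2 µM) and time it is significantly
regulated in **both** the stimulated and the unstimulated arm — any sign
combination — so the regulation cannot be routed through the drug target.

**Six response-profile classes** per (gene, compound): bipolar (sign flip
between low and high dose), common (all compounds, dose-independent), pure
off-target, additive, inverse, and pure on-target, assigned by a precedence
decision tree over the arm calls.

**Kinase overlay.** Panel rule: a kinase is an off-target when inhibited
≥ 90 % at 2 µM and ≥ 50 % at 200 nM (boundaries inclusive).  Selected
kinases' literature surrogate markers are intersected with the compound's
off-target signature; shared regulated markers flag ambiguity.

**Scorecard.** Criteria (off-target gene counts per time and total,
counter-therapeutic genes, affected / toxicity-tagged / inflammation-tagged
gene sets, off-target kinases, optional potency columns) are ranked per
column (1 = best, average ties) and summed; the lowest total wins.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data with planted ground truth (7 compounds — five "BI" indolinones, two
"Ex" pyridopyrimidinones — 5000 genes, triplicates, noise sd ≈ 0.35):

```sh
cd analysis
python 01_simulate.py && python 02_differential_expression.py
python 03_signatures.py && python 04_enrichment.py
python 05_kinase_profiling.py && python 06_scorecard.py
```

Output of `03_signatures.py` (abridged):

```
t=2h: on-target 616 genes, siRNA 514 genes, overlap 514
BI1: off-target 288 genes (2h=274, 4h=279, 12h=282), counter-therapeutic 37
BI3: off-target 174 genes (2h=170, 4h=173, 12h=172), counter-therapeutic 12
Ex1: off-target 208 genes (2h=200, 4h=206, 12h=202), counter-therapeutic 24
```

The on-target signature recovers the planted pathway genes (the siRNA
variant is a subset because the knockdown removes only 60 % of the
stimulation effect), and the off-target counts mirror the planted
promiscuity: BI1 and the two Ex compounds carry the heaviest load.
`06_scorecard.py` then prints

```
final ranking (best first): BI4 > BI2 > BI3 > BI5 > Ex2 > Ex1 > BI1
```

i.e. the selective indolinones win, the promiscuous BI1 loses despite good
potency, and the two Ex compounds are dragged down by off-target burden and
counter-therapeutic genes — the planted structure, read back off the
transcriptome.

A `phenocopy` console command exposes the same stages
(`simulate`, `de`, `on-target`, `off-target`, `classify`, `enrich`,
`kinases`, `rank`, `all`); see `phenocopy --help`.

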