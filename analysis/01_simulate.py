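#!/usr/bin/env python
"""Generate the synthetic qualification study and its side inputs.

Emulates the campaign layout: 7 compounds x 7 concentrations x 3 times in
biological triplicate under stimulation, unstimulated arms at the two
read-out concentrations, vehicle and siRNA controls; plus a 239-kinase
single-point selectivity panel planted with the published per-compound hit
counts, a kinase-to-surrogate-marker map drawn over the study's genes, and a
gene-set collection with planted chemotype structure.  Everything downstream
reads these files from results/.
"""

from common import SEED, results_dir

from phenocopy.core_io import write_gmt, write_study
from phenocopy.kinaseprof import write_panel, write_surrogate_map
from phenocopy.simdata import (
    SimConfig,
    generate_gene_sets,
    generate_kinase_panel,
    generate_study,
    truth_frame,
)

PANEL_HIT_COUNTS = {
    "BI1": 75, "BI2": 21, "BI3": 17, "BI4": 12, "BI5": 15, "Ex1": 60, "Ex2": 14,
}


def main() -> None:
    out = results_dir()
    sim = SimConfig(seed=SEED)
    study, truths = generate_study(sim)
    write_study(study, out / "matrix.tsv", out / "design.csv")
    truth_frame(truths).to_csv(out / "truth.tsv", sep="\t")

    panel, surrogate, _ = generate_kinase_panel(
        239,
        list(PANEL_HIT_COUNTS),
        PANEL_HIT_COUNTS,
        seed=SEED,
        markers_per_kinase=(0, 12),
        redundancy=0.25,
        marker_pool=study.genes,
    )
    write_panel(panel, out / "panel.csv")
    write_surrogate_map(surrogate, out / "surrogate_map.tsv")
    write_gmt(generate_gene_sets(truths, sim.compounds, seed=SEED), out / "gene_sets.gmt")

    classes = truth_frame(truths)["klass"].value_counts()
    print(f"study: {study.n_genes} genes x {study.n_samples} samples")
    print("planted classes:", classes.to_dict())
    print(f"panel: 239 kinases, planted hits {PANEL_HIT_COUNTS}")


if __name__ == "__main__":
    main()
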