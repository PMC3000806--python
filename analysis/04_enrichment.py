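#!/usr/bin/env python
"""Gene-set enrichment of the off-target signatures.

Builds the -log10 p matrix (gene sets x compounds) from Fisher's exact test
over the study-wide universe, keeps sets significant for >= 1 compound,
clusters rows/columns (manhattan, complete) and counts significant,
toxicity-tagged and inflammation-tagged sets per compound for the scorecard.
"""

import pandas as pd
from common import analysis_config, load_study, results_dir

from phenocopy.core_io import read_gmt
from phenocopy.enrichment import cluster_enrichment, enrichment_matrix


def main() -> None:
    out = results_dir()
    study = load_study()
    config = analysis_config()
    gene_sets = read_gmt(out / "gene_sets.gmt")

    signatures = {}
    for compound in study.compounds():
        table = pd.read_csv(out / f"off_target_{compound}.tsv", sep="\t")
        signatures[compound] = table["gene_id"].astype(str).tolist()

    matrix = enrichment_matrix(
        signatures, gene_sets, study.genes, threshold=config.enrichment_threshold
    )
    print(
        f"{matrix.shape[0]} of {len(gene_sets)} gene sets significant "
        f"(-log10 p > {config.enrichment_threshold:g}) for >= 1 compound"
    )
    if len(matrix) > 1:
        clustered = cluster_enrichment(matrix)
        clustered.matrix.to_csv(out / "enrichment_matrix.tsv", sep="\t")
        (out / "enrichment_rows.nwk").write_text(clustered.row_newick + "\n")
    else:
        matrix.to_csv(out / "enrichment_matrix.tsv", sep="\t")

    sig = matrix > config.enrichment_threshold
    counts = pd.DataFrame(
        {
            "significant_sets": sig.sum(),
            "toxicity_sets": sig.loc[sig.index.str.startswith("TOX")].sum(),
            "inflammation_sets": sig.loc[sig.index.str.startswith("INFLAM")].sum(),
        }
    )
    counts.index.name = "compound"
    counts.to_csv(out / "enrichment_counts.tsv", sep="\t")
    print(counts.to_string())


if __name__ == "__main__":
    main()
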