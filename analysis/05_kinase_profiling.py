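#!/usr/bin/env python
"""Kinase selectivity: panel selection rule and surrogate-marker overlay.

Applies the >=90% @ 2 uM and >=50% @ 200 nM rule per compound, overlays the
selected kinases' surrogate markers with that compound's off-target
signature, and reports marker coverage.  Writes per-compound evidence tables
and a summary for the scorecard.
"""

import pandas as pd
from common import load_study, results_dir

from phenocopy.kinaseprof import (
    coverage_summary,
    read_panel,
    read_surrogate_map,
    select_off_target_kinases,
    surrogate_overlay,
)


def main() -> None:
    out = results_dir()
    study = load_study()
    panel = read_panel(out / "panel.csv")
    surrogate = read_surrogate_map(out / "surrogate_map.tsv")

    rows = []
    for compound in study.compounds():
        off_genes = (
            pd.read_csv(out / f"off_target_{compound}.tsv", sep="\t")["gene_id"]
            .astype(str)
            .tolist()
        )
        selected = select_off_target_kinases(panel, compound)
        evidence = surrogate_overlay(selected, surrogate, off_genes)
        coverage = coverage_summary(evidence, off_genes)
        pd.DataFrame(
            [
                {
                    "kinase_id": ev.kinase_id,
                    "n_markers": ev.n_markers,
                    "n_markers_regulated": ev.n_markers_regulated,
                    "ambiguous": ev.ambiguous,
                    "regulated_markers": ";".join(ev.regulated_marker_ids),
                }
                for ev in evidence
            ]
        ).to_csv(out / f"kinase_evidence_{compound}.tsv", sep="\t", index=False)
        rows.append(
            {
                "compound": compound,
                "off_target_kinases": len(selected),
                "kinases_with_markers": sum(ev.n_markers > 0 for ev in evidence),
                "kinases_with_regulated_markers": sum(
                    ev.n_markers_regulated > 0 for ev in evidence
                ),
                "ambiguous_kinases": sum(ev.ambiguous for ev in evidence),
                "markers_total": coverage["n_markers_total"],
                "markers_regulated": coverage["n_markers_regulated"],
                "pct_regulated": coverage["pct_regulated"],
            }
        )
        print(
            f"{compound}: {len(selected)} off-target kinases; "
            f"{coverage['n_markers_regulated']}/{coverage['n_markers_total']} "
            f"markers regulated ({coverage['pct_regulated']}%)"
        )
    pd.DataFrame(rows).set_index("compound").to_csv(out / "kinase_summary.tsv", sep="\t")


if __name__ == "__main__":
    main()
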