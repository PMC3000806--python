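#!/usr/bin/env python
"""Rank the compounds on the multi-criterion scorecard.

Assembles the per-compound criteria from the earlier stages — off-target
gene counts per time and total, counter-therapeutic genes, significant /
toxicity-tagged / inflammation-tagged gene sets, off-target kinases — ranks
each criterion (1 = best), and orders compounds by rank total.
"""

import pandas as pd
from common import results_dir

from phenocopy.scorecard import build_scorecard, default_criteria


def main() -> None:
    out = results_dir()
    counts = pd.read_csv(out / "signature_counts.tsv", sep="\t", index_col=0)
    enr = pd.read_csv(out / "enrichment_counts.tsv", sep="\t", index_col=0)
    kin = pd.read_csv(out / "kinase_summary.tsv", sep="\t", index_col=0)

    times = [c[len("off_target_"):-1] for c in counts.columns
             if c.startswith("off_target_") and c.endswith("h")]
    metrics, criteria = default_criteria(
        off_target_counts={
            c: {float(t): int(counts.at[c, f"off_target_{t}h"]) for t in times}
            for c in counts.index
        },
        counter_therapeutic=counts["counter_therapeutic"].to_dict(),
        n_significant_sets=enr["significant_sets"].to_dict(),
        n_toxicity_sets=enr["toxicity_sets"].to_dict(),
        n_inflammation_sets=enr["inflammation_sets"].to_dict(),
        n_off_target_kinases=kin["off_target_kinases"].to_dict(),
    )
    card = build_scorecard(metrics, criteria)
    card.to_frame().to_csv(out / "scorecard.tsv", sep="\t")
    card.colors.to_csv(out / "scorecard_colors.tsv", sep="\t")
    print(card.to_frame().to_string())
    print("\nfinal ranking (best first):", " > ".join(card.final_order))


if __name__ == "__main__":
    main()
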