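#!/usr/bin/env python
"""Derive on-target, siRNA and off-target signatures; classify profiles.

Per time point: the three-filter on-target signature pooled over compounds
and the siRNA counterpart; per compound: the off-target signature (both arms
significant at a read-out concentration) with per-time splits, plus the
counter-therapeutic gene count.  At the earliest time the per-gene response
profiles are classified into the six classes and the treatment signatures
(compound x read-out concentration) are clustered.  Writes signature TSVs,
a per-compound count table and the treatment dendrogram.
"""

import pandas as pd
from common import analysis_config, load_study, results_dir

from phenocopy.signatures import (
    arm_contrast,
    classify_profiles,
    cluster_treatments,
    compound_call_pairs,
    counter_therapeutic_count,
    off_target_signature,
    on_target_signature,
    sirna_signature,
)


def main() -> None:
    out = results_dir()
    study = load_study()
    config = analysis_config()
    rng = config.rng()
    times = study.times()
    compounds = study.compounds()

    on_target = {}
    for t in times:
        sig = on_target_signature(study, compounds, t, config, rng=rng)
        sig.to_frame().to_csv(out / f"on_target_t{t:g}h.tsv", sep="\t")
        sirna = sirna_signature(study, t, config)
        sirna.to_frame().to_csv(out / f"sirna_t{t:g}h.tsv", sep="\t")
        on_target[t] = sig
        both = len(sig.genes & sirna.genes)
        print(
            f"t={t:g}h: on-target {len(sig)} genes, siRNA {len(sirna)} genes, "
            f"overlap {both}"
        )

    rows = []
    for compound in compounds:
        pairs = compound_call_pairs(study, compound, config)
        result = off_target_signature(pairs, compound, config)
        result.pooled.to_frame().to_csv(out / f"off_target_{compound}.tsv", sep="\t")
        wotgf_calls = [
            arm_contrast(study, compound, conc, t, stimulated=False, config=config)["call"]
            for t in times
            for conc in config.offtarget_concentrations_uM
        ]
        counter = counter_therapeutic_count(on_target[times[0]], wotgf_calls)
        rows.append(
            {
                "compound": compound,
                **{f"off_target_{t:g}h": len(result.per_time.get(t, ())) for t in times},
                "off_target_total": len(result.pooled),
                "counter_therapeutic": counter,
            }
        )
        print(
            f"{compound}: off-target {len(result.pooled)} genes "
            f"({', '.join(f'{t:g}h={len(result.per_time.get(t, ()))}' for t in times)}), "
            f"counter-therapeutic {counter}"
        )
    pd.DataFrame(rows).set_index("compound").to_csv(out / "signature_counts.tsv", sep="\t")

    t0 = times[0]
    profiles = classify_profiles(study, t0, config, on_target=on_target[t0], rng=rng)
    profiles.to_csv(out / f"profiles_t{t0:g}h.tsv", sep="\t")
    tally = profiles.apply(pd.Series.value_counts).fillna(0).astype(int)
    print(f"profile classes at t={t0:g}h:")
    print(tally.to_string())

    treatment = {
        f"{c}@{conc:g}uM": arm_contrast(study, c, conc, t0, stimulated=True, config=config)
        for c in compounds
        for conc in config.offtarget_concentrations_uM
    }
    clustering = cluster_treatments(treatment)
    (out / "treatment_dendrogram.nwk").write_text(clustering.newick + "\n")
    clustering.merge_heights().to_csv(out / "treatment_merges.tsv", sep="\t", index=False)
    print("treatment clustering leaf order:", " ".join(clustering.leaf_order))


if __name__ == "__main__":
    main()
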