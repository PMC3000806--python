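#!/usr/bin/env python
"""Stimulation response per time point.

Fits the stimulated-vs-unstimulated vehicle contrast (moderated t, BH) at
each time and reports how many genes respond — the filter-1 candidate pool
for the on-target signature.  Writes one contrast table per time.
"""

from common import analysis_config, load_study, results_dir

from phenocopy.signatures import stimulation_contrast


def main() -> None:
    out = results_dir()
    study = load_study()
    config = analysis_config()
    for t in study.times():
        table = stimulation_contrast(study, t, config)
        n_up = int((table["call"] == "up").sum())
        n_down = int((table["call"] == "down").sum())
        table.to_csv(out / f"stimulation_t{t:g}h.tsv", sep="\t")
        print(
            f"t={t:g}h: {n_up + n_down} stimulation-responsive genes "
            f"({n_up} up, {n_down} down) at adjusted p < {config.alpha}"
        )


if __name__ == "__main__":
    main()
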