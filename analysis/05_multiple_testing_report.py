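#!/usr/bin/env python
"""Multiple-testing thresholds, top-site table and Manhattan-plot data.

Bonferroni thresholds for the genome-wide and within-obesity-set families,
the 15 most significant obesity-gene sites with BH q-values, and the
plot-ready Manhattan table (to scratch/, one row per site).
"""

import json
from pathlib import Path

import pandas as pd

from methewas import manhattan_table, top_sites_report
from methewas.annotate import read_annotations
from methewas.association import read_results
from methewas.report import ThresholdSet

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    results = read_results(SCRATCH / "association.tsv")
    annotations = read_annotations(SCRATCH / "annotations.tsv")

    universe = results.join(annotations, how="inner")
    universe = universe[universe["converged"] & universe["intragenic"]]
    m_gw = len(universe)
    m_set = int(universe["obesity_flag"].sum())
    thresholds = ThresholdSet(alpha_family=0.05, m_genomewide=m_gw, m_set=m_set)

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "thresholds.json").write_text(
        json.dumps(thresholds.to_dict(), indent=2) + "\n"
    )

    top = top_sites_report(results, annotations, n_top=15)
    top.to_csv(RESULTS / "top_sites.tsv", sep="\t", index=False, float_format="%.4g")

    manhattan = manhattan_table(results, annotations)
    manhattan.to_csv(SCRATCH / "manhattan.tsv", sep="\t", index=False, float_format="%.5g")

    print(
        f"families: genome-wide m = {m_gw:,} "
        f"(threshold {thresholds.to_dict()['threshold_genomewide_2sf']}), "
        f"obesity set m = {m_set:,} "
        f"(threshold {thresholds.to_dict()['threshold_set_2sf']})"
    )
    n_pass = int(top["passes_bonferroni"].sum())
    print(f"top 15 obesity-set sites written; {n_pass} pass the within-set Bonferroni")
    print(top.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
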