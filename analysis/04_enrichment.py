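#!/usr/bin/env python
"""Test obesity-gene-set over-representation among BMI-associated sites.

Annotates the retained sites against the simulated gene model, flags sites
on the 50-gene obesity set, builds the significant-by-obesity 2x2 table and
runs the exact hypergeometric and the 10,000-draw permutation test.
"""

import json
from pathlib import Path

import pandas as pd

from methewas import annotate_sites, enrich, flag_obesity_sites, load_obesity_gene_set
from methewas.annotate import GeneModel, write_annotations
from methewas.association import read_results
from methewas.coverage import read_matrix
from methewas.enrichment import format_report

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    matrix = read_matrix(SCRATCH / "matrix.tsv")
    model = GeneModel.from_bed(SCRATCH / "cohort" / "genes.bed")
    annotations = flag_obesity_sites(
        annotate_sites(matrix.sites, model), load_obesity_gene_set()
    )
    write_annotations(annotations, SCRATCH / "annotations.tsv")

    results = read_results(SCRATCH / "association.tsv")
    result = enrich(results, annotations, alpha_site=0.05, B=10_000, seed=42)

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "enrichment.json").write_text(
        json.dumps(result.to_dict(), indent=2) + "\n"
    )
    report = format_report(result)
    (RESULTS / "enrichment.txt").write_text(report + "\n")
    print(report)


if __name__ == "__main__":
    main()
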