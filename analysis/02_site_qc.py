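#!/usr/bin/env python
"""Assemble the methylation matrix from the coverage files and apply site QC.

Cells under 10x depth become missing; sites usable in fewer than half the
subjects are dropped. The filtered matrix goes to scratch/ (large); the QC
report goes to results/.
"""

import json
from pathlib import Path

import pandas as pd

from methewas import assemble_matrix, filter_sites
from methewas.coverage import write_matrix

SCRATCH = Path(__file__).resolve().parents[1] / "scratch"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort_dir = SCRATCH / "cohort"
    samples = pd.read_csv(cohort_dir / "samples.tsv", sep="\t")
    files = {
        str(s): cohort_dir / f"{s}.cov.tsv"
        for s in samples["subject_id"].astype(str)
    }
    matrix = assemble_matrix(files, samples)
    filtered, report = filter_sites(matrix, min_coverage=10, min_subject_fraction=0.5)

    write_matrix(filtered, SCRATCH / "matrix.tsv")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "qc_report.json").write_text(
        json.dumps(report.to_dict(), indent=2) + "\n"
    )
    print(
        f"{report.n_sites_retained:,} of {report.n_sites_input:,} sites retained "
        f"({report.n_excluded_low_coverage_or_missing:,} excluded by the "
        f"<{report.min_coverage}x / <{report.min_subject_fraction:.0%}-of-subjects rule)"
    )
    print(f"post-QC cell missingness: {filtered.missingness():.1%}")


if __name__ == "__main__":
    main()
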