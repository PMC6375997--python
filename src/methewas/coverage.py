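"""Reading per-subject CpG coverage files and site-level quality control.

The on-disk dialect is the Bismark coverage format: one tab-separated record
per CpG with ``chromosome, start, end, methylation_percent, count_methylated,
count_unmethylated``, 1-based coordinates with start == end for single-CpG
records. Methylation level is always recomputed from the read counts; the
percent column in the file is only used as an integrity check.

QC follows the standard RRBS rule: a (site, subject) cell is unusable below a
minimum read depth (default 10x), and a site is dropped from the analyzable
set when it is usable in fewer than a minimum fraction of subjects (default
50%, i.e. 132 of 263).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

PERCENT_TOLERANCE = 0.05  # absolute; accommodates files rounded to 1 decimal

COVERAGE_COLUMNS = [
    "chromosome",
    "start",
    "end",
    "methylation_percent",
    "count_methylated",
    "count_unmethylated",
]


class CoverageParseError(ValueError):
    """Malformed or internally inconsistent coverage file."""


class MatrixIntegrityError(ValueError):
    """Duplicate records or subject mismatches during matrix assembly."""


class SiteCounts(NamedTuple):
    chromosome: str
    position: int  # 1-based
    count_methylated: int
    count_unmethylated: int

    @property
    def coverage(self) -> int:
        return self.count_methylated + self.count_unmethylated


def methylation_percent(counts: SiteCounts) -> float:
    """Percent methylation, 100 x methylated / (methylated + unmethylated).

    Raises ``ValueError`` on zero coverage (the level is undefined, not 0).
    """
    cov = counts.count_methylated + counts.count_unmethylated
    if cov == 0:
        raise ValueError(
            f"methylation level undefined at zero coverage "
            f"({counts.chromosome}:{counts.position})"
        )
    return 100.0 * counts.count_methylated / cov


def read_coverage_file(path: str | Path) -> list[SiteCounts]:
    """Parse one Bismark-coverage-style file into site count records.

    Records with zero total coverage are retained (they are filtered by QC,
    not rejected at parse time). A percent column that disagrees with the
    counts by more than ``PERCENT_TOLERANCE`` raises ``CoverageParseError``.
    """
    path = Path(path)
    records: list[SiteCounts] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise CoverageParseError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                pct = float(fields[3])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise CoverageParseError(f"{path}:{lineno}: {exc}") from None
            if start != end:
                raise CoverageParseError(
                    f"{path}:{lineno}: start != end ({start} != {end}); "
                    "expected single-CpG records"
                )
            if n_meth < 0 or n_unmeth < 0:
                raise CoverageParseError(f"{path}:{lineno}: negative counts")
            cov = n_meth + n_unmeth
            if cov > 0:
                recomputed = 100.0 * n_meth / cov
                if abs(recomputed - pct) > PERCENT_TOLERANCE:
                    raise CoverageParseError(
                        f"{path}:{lineno}: methylation percent {pct} "
                        f"disagrees with counts ({recomputed:.4f})"
                    )
            records.append(SiteCounts(chrom, start, n_meth, n_unmeth))
    return records


def write_coverage_file(records: Iterable[SiteCounts], path: str | Path) -> int:
    """Write records in the coverage dialect; returns the row count."""
    n = 0
    with Path(path).open("w") as fh:
        for rec in records:
            cov = rec.count_methylated + rec.count_unmethylated
            pct = 100.0 * rec.count_methylated / cov if cov else 0.0
            fh.write(
                f"{rec.chromosome}\t{rec.position}\t{rec.position}\t"
                f"{pct:.6f}\t{rec.count_methylated}\t{rec.count_unmethylated}\n"
            )
            n += 1
    return n


@dataclass
class MethylationMatrix:
    """Sites x subjects methylation levels with per-cell read depth.

    ``percent`` holds methylation in [0, 100] with NaN for missing cells;
    ``coverage`` holds read depth (0 where a subject has no record for a
    site). Rows are indexed by (chromosome, position); columns are subject
    ids in sample-table order.
    """

    percent: pd.DataFrame
    coverage: pd.DataFrame | None = None

    @property
    def n_sites(self) -> int:
        return self.percent.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.percent.shape[1]

    @property
    def subjects(self) -> list[str]:
        return list(self.percent.columns)

    @property
    def sites(self) -> pd.MultiIndex:
        return self.percent.index

    def missingness(self) -> float:
        return float(self.percent.isna().to_numpy().mean())


@dataclass
class QCReport:
    n_sites_input: int
    n_sites_retained: int
    n_excluded_low_coverage_or_missing: int
    min_coverage: int
    min_subject_fraction: float

    def __post_init__(self) -> None:
        if (
            self.n_sites_retained + self.n_excluded_low_coverage_or_missing
            != self.n_sites_input
        ):
            raise ValueError("QCReport counts do not add up")

    def to_dict(self) -> dict:
        return {
            "n_sites_input": self.n_sites_input,
            "n_sites_retained": self.n_sites_retained,
            "n_excluded_low_coverage_or_missing": self.n_excluded_low_coverage_or_missing,
            "min_coverage": self.min_coverage,
            "min_subject_fraction": self.min_subject_fraction,
        }


def assemble_matrix(
    files: Mapping[str, str | Path] | Sequence[str | Path],
    sample_table: pd.DataFrame,
) -> MethylationMatrix:
    """Combine per-subject coverage files into one cross-subject matrix.

    ``files`` maps subject id -> path; a plain sequence of paths uses the
    file stem (minus a trailing ``.cov``) as the subject id. The site set is
    the union over subjects; absent cells get coverage 0 and missing percent.
    """
    if not isinstance(files, Mapping):
        files = {_subject_from_path(p): p for p in files}
    known = set(sample_table["subject_id"].astype(str))
    unknown = sorted(set(files) - known)
    if unknown:
        raise MatrixIntegrityError(
            f"subjects in coverage files but not in sample table: {unknown}"
        )

    frames = []
    for subject in files:  # insertion order; reordered to table order below
        recs = read_coverage_file(files[subject])
        df = pd.DataFrame(recs, columns=SiteCounts._fields)
        dup = df.duplicated(subset=["chromosome", "position"])
        if dup.any():
            first = df.loc[dup.idxmax()]
            raise MatrixIntegrityError(
                f"duplicate record for {first.chromosome}:{first.position} "
                f"in subject {subject}"
            )
        df["subject"] = subject
        frames.append(df)
    if not frames:
        raise MatrixIntegrityError("no coverage files supplied")
    long = pd.concat(frames, ignore_index=True)
    long["coverage"] = long["count_methylated"] + long["count_unmethylated"]
    cov = long.pivot_table(
        index=["chromosome", "position"],
        columns="subject",
        values="coverage",
        fill_value=0,
        aggfunc="first",
    ).sort_index()
    meth = long.pivot_table(
        index=["chromosome", "position"],
        columns="subject",
        values="count_methylated",
        aggfunc="first",
    ).sort_index()
    # subjects with a file but in sample-table order; subjects with no file
    # would be all-missing columns and are not invented here
    order = [s for s in sample_table["subject_id"].astype(str) if s in files]
    cov = cov.reindex(columns=order, fill_value=0).astype(np.int64)
    meth = meth.reindex(columns=order)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * meth.to_numpy(dtype=float) / cov.to_numpy(dtype=float)
    percent = pd.DataFrame(pct, index=cov.index, columns=cov.columns)
    percent[cov == 0] = np.nan
    return MethylationMatrix(percent=percent, coverage=cov)


def _subject_from_path(path: str | Path) -> str:
    stem = Path(path).name
    for suffix in (".tsv", ".txt", ".cov"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
    return stem


def filter_sites(
    matrix: MethylationMatrix,
    min_coverage: int = 10,
    min_subject_fraction: float = 0.5,
) -> tuple[MethylationMatrix, QCReport]:
    """Apply the depth and subject-availability filters.

    Cells below ``min_coverage`` reads become missing; sites then usable in
    fewer than ``ceil(min_subject_fraction * n_subjects)`` subjects are
    removed (263 subjects at 0.5 -> the 132-subject rule). Idempotent.
    """
    if not (0.0 < min_subject_fraction <= 1.0):
        raise ValueError("min_subject_fraction must be in (0, 1]")
    if min_coverage < 0:
        raise ValueError("min_coverage must be nonnegative")
    if matrix.coverage is None:
        raise ValueError("matrix has no coverage information; cannot QC")

    cov = matrix.coverage
    percent = matrix.percent.where(cov >= min_coverage)
    threshold = math.ceil(min_subject_fraction * matrix.n_subjects)
    present = percent.notna().sum(axis=1)
    keep = present >= threshold
    filtered = MethylationMatrix(
        percent=percent.loc[keep], coverage=cov.loc[keep]
    )
    report = QCReport(
        n_sites_input=matrix.n_sites,
        n_sites_retained=int(keep.sum()),
        n_excluded_low_coverage_or_missing=int((~keep).sum()),
        min_coverage=min_coverage,
        min_subject_fraction=min_subject_fraction,
    )
    return filtered, report


def write_matrix(matrix: MethylationMatrix, path: str | Path) -> None:
    """Write the percent matrix as TSV (chromosome, position, then one
    column per subject; NA for missing)."""
    out = matrix.percent.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6f")


def read_matrix(path: str | Path) -> MethylationMatrix:
    """Read a matrix written by :func:`write_matrix`.

    Coverage is not stored in the TSV; the result carries ``coverage=None``
    and supports association analysis but not re-running the depth filter.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df = df.set_index(["chromosome", "position"])
    df.columns = df.columns.astype(str)
    return MethylationMatrix(percent=df, coverage=None)
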