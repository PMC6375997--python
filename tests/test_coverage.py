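"""Coverage-file parsing, matrix assembly and the site QC filters."""

import math

import numpy as np
import pandas as pd
import pytest

from methewas.coverage import (
    CoverageParseError,
    MatrixIntegrityError,
    MethylationMatrix,
    SiteCounts,
    assemble_matrix,
    filter_sites,
    methylation_percent,
    read_coverage_file,
    read_matrix,
    write_coverage_file,
    write_matrix,
)


@pytest.mark.parametrize(
    "meth, unmeth, expected",
    [(5, 5, 50.0), (10, 0, 100.0), (0, 10, 0.0), (7, 3, 70.0), (1, 3, 25.0)],
)
def test_methylation_percent_from_counts(meth, unmeth, expected):
    counts = SiteCounts("chr1", 100, meth, unmeth)
    assert methylation_percent(counts) == pytest.approx(expected)


def test_methylation_percent_undefined_at_zero_coverage():
    with pytest.raises(ValueError, match="zero coverage"):
        methylation_percent(SiteCounts("chr1", 100, 0, 0))


def test_methylation_percent_bounds():
    rng = np.random.default_rng(0)
    for _ in range(200):
        m, u = int(rng.integers(0, 50)), int(rng.integers(0, 50))
        if m + u == 0:
            continue
        pct = methylation_percent(SiteCounts("chr1", 1, m, u))
        assert 0.0 <= pct <= 100.0
        assert (pct == 0.0) == (m == 0)
        assert (pct == 100.0) == (u == 0)


class TestReadCoverageFile:
    def test_parses_symmetric_record(self, tmp_path):
        path = tmp_path / "s.cov.tsv"
        path.write_text("chr6\t100903612\t100903612\t50.0\t5\t5\n")
        (rec,) = read_coverage_file(path)
        assert rec == SiteCounts("chr6", 100903612, 5, 5)

    def test_zero_coverage_record_retained(self, tmp_path):
        path = tmp_path / "s.cov.tsv"
        path.write_text("chr1\t10\t10\t0.0\t0\t0\n")
        (rec,) = read_coverage_file(path)
        assert rec.coverage == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "s.cov.tsv"
        path.write_text("chr1\t10\t10\t50.0\t1\t1\nchr1\t20\t20\t50.0\t1\n")
        with pytest.raises(CoverageParseError, match=":2:"):
            read_coverage_file(path)

    def test_percent_count_disagreement_rejected(self, tmp_path):
        path = tmp_path / "s.cov.tsv"
        path.write_text("chr1\t10\t10\t80.0\t5\t5\n")
        with pytest.raises(CoverageParseError, match="disagrees"):
            read_coverage_file(path)

    def test_percent_rounded_to_one_decimal_accepted(self, tmp_path):
        path = tmp_path / "s.cov.tsv"
        path.write_text("chr1\t10\t10\t33.3\t1\t2\n")
        (rec,) = read_coverage_file(path)
        assert rec.count_methylated == 1

    def test_start_end_mismatch_rejected(self, tmp_path):
        path = tmp_path / "s.cov.tsv"
        path.write_text("chr1\t10\t11\t50.0\t1\t1\n")
        with pytest.raises(CoverageParseError, match="start != end"):
            read_coverage_file(path)

    def test_write_read_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        records = [
            SiteCounts("chr1", int(pos), int(m), int(u))
            for pos, m, u in zip(
                np.sort(rng.choice(10_000, 1000, replace=False)) + 1,
                rng.integers(0, 60, 1000),
                rng.integers(0, 60, 1000),
            )
        ]
        path = tmp_path / "rt.cov.tsv"
        assert write_coverage_file(records, path) == 1000
        assert read_coverage_file(path) == records


class TestAssembleMatrix:
    def _write(self, tmp_path, subject, rows):
        path = tmp_path / f"{subject}.cov.tsv"
        write_coverage_file(rows, path)
        return path

    def _samples(self, ids):
        return pd.DataFrame(
            {
                "subject_id": ids,
                "age": 16.0,
                "sex": "male",
                "race": "white",
                "batch": 1,
                "bmi_percentile": 50.0,
            }
        )

    def test_disjoint_site_lists_union_with_half_missing(self, tmp_path):
        a = [SiteCounts("chr1", p, 5, 5) for p in (10, 20, 30)]
        b = [SiteCounts("chr1", p, 5, 5) for p in (40, 50, 60)]
        files = {
            "A": self._write(tmp_path, "A", a),
            "B": self._write(tmp_path, "B", b),
        }
        matrix = assemble_matrix(files, self._samples(["A", "B"]))
        assert matrix.n_sites == 6
        assert matrix.missingness() == pytest.approx(0.5)
        assert (matrix.coverage.to_numpy() == 0).sum() == 6

    def test_shared_site_has_no_missing_cells(self, tmp_path):
        ids = [f"S{i}" for i in range(12)]
        files = {
            s: self._write(tmp_path, s, [SiteCounts("chr2", 999, 7, 3)])
            for s in ids
        }
        matrix = assemble_matrix(files, self._samples(ids))
        assert matrix.n_sites == 1
        assert not matrix.percent.isna().any().any()
        assert np.allclose(matrix.percent.to_numpy(), 70.0)

    def test_unknown_subject_rejected(self, tmp_path):
        files = {"X": self._write(tmp_path, "X", [SiteCounts("chr1", 1, 1, 1)])}
        with pytest.raises(MatrixIntegrityError, match="not in sample table"):
            assemble_matrix(files, self._samples(["A"]))

    def test_duplicate_record_rejected(self, tmp_path):
        rows = [SiteCounts("chr1", 5, 1, 1), SiteCounts("chr1", 5, 2, 2)]
        files = {"A": self._write(tmp_path, "A", rows)}
        with pytest.raises(MatrixIntegrityError, match="duplicate"):
            assemble_matrix(files, self._samples(["A"]))

    def test_file_order_does_not_change_matrix(self, tmp_path):
        rng = np.random.default_rng(3)
        ids = ["A", "B", "C"]
        files = {}
        for s in ids:
            pos = np.sort(rng.choice(500, 40, replace=False)) + 1
            rows = [
                SiteCounts("chr1", int(p), int(m), int(u))
                for p, m, u in zip(
                    pos, rng.integers(0, 30, 40), rng.integers(0, 30, 40)
                )
            ]
            files[s] = self._write(tmp_path, s, rows)
        samples = self._samples(ids)
        m1 = assemble_matrix(files, samples)
        m2 = assemble_matrix(dict(reversed(files.items())), samples)
        pd.testing.assert_frame_equal(m1.percent, m2.percent)
        pd.testing.assert_frame_equal(m1.coverage, m2.coverage)


class TestFilterSites:
    def _matrix(self, coverage: np.ndarray) -> MethylationMatrix:
        n_sites, n_subj = coverage.shape
        index = pd.MultiIndex.from_arrays(
            [["chr1"] * n_sites, range(1, n_sites + 1)],
            names=["chromosome", "position"],
        )
        cols = [f"S{i}" for i in range(n_subj)]
        cov = pd.DataFrame(coverage, index=index, columns=cols)
        percent = pd.DataFrame(
            np.where(coverage > 0, 50.0, np.nan), index=index, columns=cols
        )
        return MethylationMatrix(percent=percent, coverage=cov)

    def test_hand_enumerated_fixture(self):
        """10 sites, 4 subjects, threshold 2-of-4 usable at >=10x.

        Sites 0-6 stay usable in >=2 subjects. Site 7 is assayed everywhere
        but below 10x in 3 subjects (killed by the coverage mask); site 8
        simply has records for only 1 subject; site 9 fails both ways.
        Hand enumeration: 7 retained, 3 excluded.
        """
        cov = np.array(
            [
                [30, 30, 30, 30],
                [10, 10, 0, 0],
                [10, 9, 10, 9],
                [15, 0, 15, 0],
                [10, 10, 10, 10],
                [50, 50, 9, 9],
                [12, 12, 12, 0],
                [9, 9, 9, 30],   # low coverage: only 1 usable
                [25, 0, 0, 0],   # absent from 3 subjects
                [9, 0, 0, 8],    # both failure modes
            ]
        )
        matrix = self._matrix(cov)
        filtered, report = filter_sites(matrix, 10, 0.5)
        assert report.n_sites_input == 10
        assert report.n_sites_retained == 7
        assert report.n_excluded_low_coverage_or_missing == 3
        retained_positions = filtered.percent.index.get_level_values("position")
        assert list(retained_positions) == [1, 2, 3, 4, 5, 6, 7]

    def test_subject_threshold_is_ceiling_of_fraction(self):
        # 263 subjects at 50% -> a site needs >= 132 usable subjects
        assert math.ceil(0.5 * 263) == 132
        rng = np.random.default_rng(1)
        n_subj = 263
        cov = np.full((2, n_subj), 0)
        cov[0, :132] = 30  # exactly at threshold: retained
        cov[1, :131] = 30  # one short: excluded
        filtered, report = filter_sites(self._matrix(cov), 10, 0.5)
        assert report.n_sites_retained == 1
        assert filtered.percent.index.get_level_values("position")[0] == 1

    def test_fully_covered_site_passes_unchanged(self):
        cov = np.full((3, 5), 30)
        matrix = self._matrix(cov)
        filtered, report = filter_sites(matrix, 10, 0.5)
        assert report.n_sites_retained == 3
        pd.testing.assert_frame_equal(filtered.percent, matrix.percent)

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        cov = rng.integers(0, 40, size=(60, 9))
        once, rep1 = filter_sites(self._matrix(cov), 10, 0.5)
        twice, rep2 = filter_sites(once, 10, 0.5)
        pd.testing.assert_frame_equal(once.percent, twice.percent)
        assert rep2.n_sites_retained == rep1.n_sites_retained
        assert rep2.n_excluded_low_coverage_or_missing == 0

    def test_report_conserves_counts(self):
        rng = np.random.default_rng(13)
        for trial in range(20):
            cov = rng.integers(0, 25, size=(rng.integers(1, 50), 6))
            _, report = filter_sites(self._matrix(cov), 10, 0.5)
            assert (
                report.n_sites_retained
                + report.n_excluded_low_coverage_or_missing
                == report.n_sites_input
            )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="min_subject_fraction"):
            filter_sites(self._matrix(np.full((2, 2), 30)), 10, 0.0)


def test_matrix_tsv_round_trip(tmp_path, small_cohort):
    filtered, _ = filter_sites(small_cohort.matrix)
    path = tmp_path / "m.tsv"
    write_matrix(filtered, path)
    back = read_matrix(path)
    assert back.percent.shape == filtered.percent.shape
    np.testing.assert_allclose(
        back.percent.to_numpy(), filtered.percent.to_numpy(), atol=1e-6
    )


def test_cohort_round_trip_matches_generator_truth(small_cohort, small_cohort_dir):
    """Assembling the written coverage files reproduces the in-memory
    matrix exactly (after the same 10x mask)."""
    samples = small_cohort.sample_table
    files = {
        str(s): small_cohort_dir / f"{s}.cov.tsv"
        for s in samples["subject_id"].astype(str)
    }
    assembled = assemble_matrix(files, samples)
    # mask cells under 10x without dropping any site (fraction -> tiny)
    masked = assembled.percent.where(assembled.coverage >= 10)
    truth = small_cohort.matrix.percent
    shared = truth.index.intersection(masked.index)
    # sites absent everywhere (all-zero depth) never reach the files
    assert len(shared) == len(masked.index)
    np.testing.assert_allclose(
        masked.loc[shared].to_numpy(), truth.loc[shared].to_numpy(), atol=5e-5
    )
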