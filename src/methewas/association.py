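"""Per-site linear models of BMI percentile on methylation.

For every CpG site the model is ordinary least squares

    bmi_percentile ~ intercept + methylation/10 + age + race + sex + batch

on the subjects with a usable methylation value at that site (complete-case
per site, matching coverage-driven missingness handling). The methylation
regressor enters divided by 10, so the reported coefficient is the change in
BMI percentile per 10% increase in methylation. Two-sided p-values come from
the t distribution with the residual degrees of freedom.

A site is *non-converged* (no estimates) when too few subjects remain, the
design is rank-deficient, or methylation is constant across subjects.

Also here: the genomic inflation factor (median chi-square statistic over
the chi-square-1 median, 0.4549...) and the Mann-Whitney missingness-bias
check comparing the outcome between missing and non-missing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.45493642...

DEFAULT_COVARIATES = ("age", "race", "sex", "batch")


class SubjectMismatchError(ValueError):
    """Matrix columns and sample table disagree."""


@dataclass(frozen=True)
class AssociationResult:
    chromosome: str
    position: int
    beta_per_10pct: float
    se: float
    p_value: float
    n_used: int
    converged: bool


@dataclass(frozen=True)
class InflationReport:
    lambda_gc: float
    n_pvalues: int


def build_design(
    samples: pd.DataFrame, covariates: Sequence[str] = DEFAULT_COVARIATES
) -> np.ndarray:
    """Covariate block of the design matrix (no intercept, no methylation).

    race -> indicator of "white", sex -> indicator of "male", batch -> fixed
    indicators with the first batch as reference; age enters as-is.
    """
    cols: list[np.ndarray] = []
    for cov in covariates:
        if cov == "age":
            cols.append(samples["age"].to_numpy(dtype=float))
        elif cov == "race":
            cols.append(
                (samples["race"].astype(str).str.lower() == "white").to_numpy(float)
            )
        elif cov == "sex":
            cols.append(
                (samples["sex"].astype(str).str.lower() == "male").to_numpy(float)
            )
        elif cov == "batch":
            batches = pd.Categorical(samples["batch"])
            for level in batches.categories[1:]:
                cols.append((batches == level).astype(float))
        else:
            cols.append(samples[cov].to_numpy(dtype=float))
    if not cols:
        return np.empty((len(samples), 0))
    return np.column_stack(cols)


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Least squares with textbook standard errors.

    Returns (beta, se, rank). Uses a QR-based solve; the covariance of the
    estimates is s^2 (X'X)^-1 with s^2 = RSS / (n - rank).
    """
    n, k = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - rank
    if dof <= 0:
        return beta, np.full(k, np.nan), rank
    s2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(xtx_inv), 0, None) * s2)
    return beta, se, rank


def fit_site(
    methylation: np.ndarray | pd.Series,
    outcome: np.ndarray | pd.Series,
    covariates: np.ndarray,
    chromosome: str = "NA",
    position: int = 0,
) -> AssociationResult:
    """Fit one site. ``methylation`` is percent (0-100) with NaN missing;
    ``covariates`` is the pre-built covariate block (n x c)."""
    meth = np.asarray(methylation, dtype=float)
    y_all = np.asarray(outcome, dtype=float)
    mask = ~np.isnan(meth)
    n_used = int(mask.sum())
    k_params = 2 + covariates.shape[1]  # intercept + methylation + covariates

    def failed() -> AssociationResult:
        return AssociationResult(
            chromosome, int(position), np.nan, np.nan, np.nan, n_used, False
        )

    if n_used < k_params + 2:
        return failed()
    x = meth[mask] / 10.0  # per-10% scale
    if np.ptp(x) == 0.0:
        return failed()
    X = np.column_stack([np.ones(n_used), x, covariates[mask]])
    beta, se, rank = _ols(X, y_all[mask])
    if rank < X.shape[1] or not np.isfinite(se[1]) or se[1] <= 0:
        return failed()
    dof = n_used - rank
    t = beta[1] / se[1]
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    return AssociationResult(
        chromosome, int(position), float(beta[1]), float(se[1]), p, n_used, True
    )


def fit_all(matrix, samples: pd.DataFrame, covariates=DEFAULT_COVARIATES) -> pd.DataFrame:
    """Fit every site of a :class:`~methewas.coverage.MethylationMatrix`.

    Returns a frame indexed by (chromosome, position) with columns
    beta_per_10pct, se, p_value, n_used, converged. Deterministic, and
    invariant to site order.

    Sites with no missing values share the same design, so they are fit in
    one vectorized pass by first projecting the outcome and all methylation
    columns off the covariates (Frisch-Waugh-Lovell); the per-site loop is
    only taken for incomplete sites. Both paths give identical estimates.
    """
    subj = [str(s) for s in samples["subject_id"]]
    if list(matrix.percent.columns) != subj:
        if set(matrix.percent.columns) != set(subj):
            raise SubjectMismatchError(
                "matrix subjects and sample table subjects differ"
            )
        matrix_percent = matrix.percent[subj]
    else:
        matrix_percent = matrix.percent
    y = samples["bmi_percentile"].to_numpy(dtype=float)
    cov = build_design(samples, covariates)

    values = matrix_percent.to_numpy(dtype=float)
    complete = ~np.isnan(values).any(axis=1)
    n, c = values.shape[1], cov.shape[1]
    rows: dict[tuple[str, int], AssociationResult] = {}

    if complete.any():
        rows.update(
            _fit_complete_block(
                matrix_percent.index[complete], values[complete], y, cov
            )
        )
    for i in np.flatnonzero(~complete):
        chrom, pos = matrix_percent.index[i]
        rows[(chrom, pos)] = fit_site(values[i], y, cov, chrom, pos)

    out = pd.DataFrame(
        [rows[site] for site in matrix_percent.index],
        index=matrix_percent.index,
    )
    out = out.drop(columns=["chromosome", "position"])
    out.index.names = ["chromosome", "position"]
    return out


def _fit_complete_block(index, values: np.ndarray, y: np.ndarray, cov: np.ndarray):
    """Vectorized OLS for fully observed sites via covariate projection."""
    n = values.shape[1]
    k_params = 2 + cov.shape[1]
    Z = np.column_stack([np.ones(n), cov])  # shared nuisance design
    rank_z = np.linalg.matrix_rank(Z)
    if rank_z < Z.shape[1]:
        # collinear covariates: every site's design is rank-deficient
        return {
            (chrom, pos): AssociationResult(
                chrom, int(pos), np.nan, np.nan, np.nan, n, False
            )
            for chrom, pos in index
        }
    Q, _ = np.linalg.qr(Z)
    ry = y - Q @ (Q.T @ y)
    X = values.T / 10.0  # n x m, per-10% scale
    RX = X - Q @ (Q.T @ X)
    sxx = np.einsum("ij,ij->j", RX, RX)
    sxy = RX.T @ ry
    dof = n - rank_z - 1
    results = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = sxy / sxx
        rss = float(ry @ ry) - beta * sxy
        s2 = rss / dof
        se = np.sqrt(s2 / sxx)
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    constant = np.ptp(values, axis=1) == 0.0
    degenerate = constant | (sxx <= 1e-12 * n) | (n < k_params + 2)
    for j, (chrom, pos) in enumerate(index):
        if degenerate[j] or not np.isfinite(se[j]) or se[j] <= 0:
            results[(chrom, pos)] = AssociationResult(
                chrom, int(pos), np.nan, np.nan, np.nan, n, False
            )
        else:
            results[(chrom, pos)] = AssociationResult(
                chrom,
                int(pos),
                float(beta[j]),
                float(se[j]),
                float(p[j]),
                n,
                True,
            )
    return results


def genomic_inflation(p_values) -> InflationReport:
    """Genomic inflation factor: median chi-square-1 quantile of the
    p-values over the chi-square-1 median (lambda = 1 iff median p = 0.5)."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return InflationReport(
        lambda_gc=float(np.median(chi) / CHI2_1_MEDIAN), n_pvalues=int(p.size)
    )


def missingness_bias_check(
    matrix,
    samples: pd.DataFrame,
    sites: Sequence[tuple[str, int]],
    alpha: float = 0.05,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Mann-Whitney U comparison of BMI percentile between subjects missing
    and not missing each named site.

    Exact enumeration when both groups have at most ``exact_max_n`` subjects,
    normal approximation with tie correction otherwise. A site with an empty
    missing or present group is flagged not testable.
    """
    y = samples.set_index(samples["subject_id"].astype(str))["bmi_percentile"]
    rows = []
    for chrom, pos in sites:
        if (chrom, pos) not in matrix.percent.index:
            raise KeyError(f"site {chrom}:{pos} not in matrix")
        row = matrix.percent.loc[(chrom, pos)]
        missing = y[row[row.isna()].index].to_numpy(float)
        present = y[row[row.notna()].index].to_numpy(float)
        if len(missing) == 0 or len(present) == 0:
            rows.append((chrom, pos, len(missing), len(present), np.nan, False, False))
            continue
        method = (
            "exact"
            if max(len(missing), len(present)) <= exact_max_n
            and len(np.unique(np.concatenate([missing, present])))
            == len(missing) + len(present)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(
            missing, present, alternative="two-sided", method=method
        )
        p = float(res.pvalue)
        rows.append((chrom, pos, len(missing), len(present), p, True, p < alpha))
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "position",
            "n_missing",
            "n_present",
            "p_value",
            "testable",
            "biased",
        ],
    ).set_index(["chromosome", "position"])


def write_results(results: pd.DataFrame, path) -> None:
    results.reset_index().to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["converged"] = df["converged"].astype(bool)
    return df.set_index(["chromosome", "position"])
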