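"""Multiple-testing thresholds, BH q-values, and ranked/plot-ready tables.

Two Bonferroni families are reported: genome-wide (all converged intragenic
sites; 0.05/103,466 -> 4.8E-07 at the published scale) and within the
obesity gene set (0.05/308 -> 1.6E-04). Benjamini-Hochberg q-values support
an explicit family size m that may exceed the number of p-values supplied,
for the case where only the smallest members of the family are listed (each
unlisted p is then guaranteed not to alter the step-up minimum over the
listed ranks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ThresholdSet:
    alpha_family: float
    m_genomewide: int
    m_set: int

    def __post_init__(self) -> None:
        if self.m_genomewide < 1 or self.m_set < 1:
            raise ValueError("family sizes must be >= 1")

    @property
    def threshold_genomewide(self) -> float:
        return self.alpha_family / self.m_genomewide

    @property
    def threshold_set(self) -> float:
        return self.alpha_family / self.m_set

    def to_dict(self) -> dict:
        return {
            "alpha_family": self.alpha_family,
            "m_genomewide": self.m_genomewide,
            "m_set": self.m_set,
            "threshold_genomewide": self.threshold_genomewide,
            "threshold_set": self.threshold_set,
            "threshold_genomewide_2sf": format_threshold(self.threshold_genomewide),
            "threshold_set_2sf": format_threshold(self.threshold_set),
        }


def bonferroni_threshold(m: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    return alpha / m


def format_threshold(x: float) -> str:
    """Two-significant-figure scientific notation, e.g. 4.8E-07."""
    return f"{x:.1E}"


def bh_qvalues(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the family size (default: the list length). m may exceed the
    list length when only the smallest p-values of the family are supplied;
    the caller guarantees every unlisted p exceeds the largest listed one.
    Output is aligned to the input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-d sequence")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the list length")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


_CHROM_SPECIAL = {"X": 23, "Y": 24, "M": 25, "MT": 25}


def _chrom_key(chrom: str) -> tuple[int, str]:
    name = str(chrom)
    stripped = name[3:] if name.lower().startswith("chr") else name
    if stripped.isdigit():
        return (int(stripped), "")
    return (_CHROM_SPECIAL.get(stripped.upper(), 1000), stripped)


def manhattan_table(results: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready table for the genome-wide Manhattan view.

    One row per converged intragenic site: chromosome, position, cumulative
    genome coordinate (chromosomes laid end to end in natural order),
    -log10 p, obesity flag.
    """
    merged = results.join(annotations, how="inner")
    pool = merged[merged["converged"] & merged["intragenic"]].reset_index()
    chroms = sorted(pool["chromosome"].unique(), key=_chrom_key)
    sizes = pool.groupby("chromosome")["position"].max()
    offsets, running = {}, 0
    for chrom in chroms:
        offsets[chrom] = running
        running += int(sizes[chrom])
    pool["chrom_order"] = pool["chromosome"].map({c: i for i, c in enumerate(chroms)})
    pool = pool.sort_values(["chrom_order", "position"], kind="stable")
    pool["cumulative_position"] = (
        pool["chromosome"].map(offsets) + pool["position"]
    )
    pool["neg_log10_p"] = -np.log10(pool["p_value"])
    return pool[
        [
            "chromosome",
            "position",
            "cumulative_position",
            "neg_log10_p",
            "obesity_flag",
        ]
    ].reset_index(drop=True)


def top_sites_report(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    n_top: int = 15,
    alpha_family: float = 0.05,
) -> pd.DataFrame:
    """Ranked table of the most significant obesity-gene sites.

    q-values and the Bonferroni pass flag use the within-set family size
    m = number of converged obesity-flagged sites. Returns all sites (with a
    warning) if fewer than ``n_top`` qualify.
    """
    merged = results.join(annotations, how="inner")
    pool = merged[merged["converged"] & merged["obesity_flag"].astype(bool)]
    if pool.empty:
        raise ValueError("no converged obesity-set sites to rank")
    m_set = len(pool)
    pool = pool.sort_values("p_value", kind="stable").reset_index()
    pool["q_bh"] = bh_qvalues(pool["p_value"].to_numpy(), m=m_set)
    threshold = bonferroni_threshold(m_set, alpha_family)
    pool["passes_bonferroni"] = pool["p_value"] < threshold
    if len(pool) < n_top:
        import warnings

        warnings.warn(
            f"only {len(pool)} obesity-set sites available (requested {n_top})",
            stacklevel=2,
        )
    top = pool.head(n_top)
    return top[
        [
            "chromosome",
            "position",
            "gene_symbols",
            "beta_per_10pct",
            "se",
            "p_value",
            "q_bh",
            "passes_bonferroni",
        ]
    ].rename(columns={"gene_symbols": "gene"})
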