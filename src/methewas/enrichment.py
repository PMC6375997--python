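"""Obesity-gene-set over-representation among BMI-associated CpG sites.

The universe is the converged intragenic sites (N). K of them lie on
obesity-set genes, n reach the site-level significance cutoff (strict
p < 0.05), and k do both. Over-representation is tested two ways:

* exact upper-tail hypergeometric probability P(X >= k), accumulated in log
  space so large universes do not underflow;
* a permutation null that re-draws the K set labels uniformly without
  replacement B times (default 10,000) and counts permutations whose overlap
  reaches k, with the add-one estimator p = (1 + #{>= k}) / (B + 1).

Site-label resampling is the default permutation unit and converges to the
hypergeometric answer; gene-label permutation is offered because CpG sites
within a gene are correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


@dataclass(frozen=True)
class EnrichmentTable:
    """2x2 significant-by-obesity-gene site counts with margins."""

    n_total_intragenic: int  # N
    n_obesity_sites: int  # K
    n_significant: int  # n
    n_overlap: int  # k
    alpha_site: float = 0.05

    def __post_init__(self) -> None:
        N, K, n, k = (
            self.n_total_intragenic,
            self.n_obesity_sites,
            self.n_significant,
            self.n_overlap,
        )
        cells = self.cells
        if K > N or n > N or k > min(K, n) or any(v < 0 for v in cells):
            raise ValueError(
                f"inconsistent 2x2 margins: N={N}, K={K}, n={n}, k={k}"
            )

    @property
    def cells(self) -> tuple[int, int, int, int]:
        """(sig & obesity, sig & background, nonsig & obesity, nonsig & background)."""
        N, K, n, k = (
            self.n_total_intragenic,
            self.n_obesity_sites,
            self.n_significant,
            self.n_overlap,
        )
        return (k, n - k, K - k, N - K - n + k)

    @property
    def significant_fraction_obesity(self) -> float:
        """Share of obesity-gene sites reaching the cutoff (k / K)."""
        return self.n_overlap / self.n_obesity_sites

    @property
    def significant_fraction_background(self) -> float:
        """Share of background sites reaching the cutoff ((n-k) / (N-K))."""
        return (self.n_significant - self.n_overlap) / (
            self.n_total_intragenic - self.n_obesity_sites
        )


@dataclass(frozen=True)
class EnrichmentResult:
    table: EnrichmentTable
    p_hypergeometric: float
    p_permutation: float
    n_permutations: int
    seed: int
    unit: str
    null_overlap_mean: float
    null_overlap_sd: float

    def to_dict(self) -> dict:
        return {
            "N_intragenic": self.table.n_total_intragenic,
            "K_obesity_sites": self.table.n_obesity_sites,
            "n_significant": self.table.n_significant,
            "k_overlap": self.table.n_overlap,
            "alpha_site": self.table.alpha_site,
            "significant_fraction_obesity": self.table.significant_fraction_obesity,
            "significant_fraction_background": self.table.significant_fraction_background,
            "p_hypergeometric": self.p_hypergeometric,
            "p_permutation": self.p_permutation,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "unit": self.unit,
            "null_overlap_mean": self.null_overlap_mean,
            "null_overlap_sd": self.null_overlap_sd,
        }


def build_table(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    alpha_site: float = 0.05,
) -> EnrichmentTable:
    """Cross-tabulate converged intragenic sites by significance (strict
    p < alpha_site) and obesity-set membership."""
    merged = results.join(annotations, how="inner")
    pool = merged[merged["converged"] & merged["intragenic"]]
    if pool.empty:
        raise ValueError("no converged intragenic sites; cannot build table")
    sig = pool["p_value"] < alpha_site
    obe = pool["obesity_flag"].astype(bool)
    return EnrichmentTable(
        n_total_intragenic=int(len(pool)),
        n_obesity_sites=int(obe.sum()),
        n_significant=int(sig.sum()),
        n_overlap=int((sig & obe).sum()),
        alpha_site=alpha_site,
    )


def hypergeometric_test(table: EnrichmentTable) -> float:
    """Exact upper tail P(X >= k), X ~ Hypergeom(N, K, n), in log space."""
    N, K, n, k = (
        table.n_total_intragenic,
        table.n_obesity_sites,
        table.n_significant,
        table.n_overlap,
    )
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    log_tail = logsumexp(stats.hypergeom.logpmf(support, N, K, n))
    return float(min(1.0, np.exp(log_tail)))


def permutation_test(
    significant_flags: Sequence[bool] | np.ndarray,
    obesity_flags: Sequence[bool] | np.ndarray,
    B: int = 10_000,
    seed: int = 0,
    unit: str = "site",
    site_genes: Sequence[str] | None = None,
) -> EnrichmentResult:
    """Permutation over-representation test on the intragenic site universe.

    unit="site": redraw the K obesity-site labels uniformly without
    replacement among the N sites each permutation. unit="gene": permute the
    obesity/background labels over genes (``site_genes`` gives each site's
    comma-joined gene symbols) and recount flagged sites. One-sided p with
    the (1 + b) / (B + 1) estimator; deterministic given the seed.
    """
    if B < 1:
        raise ValueError("number of permutations must be >= 1")
    sig = np.asarray(significant_flags, dtype=bool)
    obe = np.asarray(obesity_flags, dtype=bool)
    if sig.shape != obe.shape:
        raise ValueError("flag vectors must have equal length")
    N = sig.size
    K = int(obe.sum())
    n = int(sig.sum())
    k_obs = int((sig & obe).sum())
    rng = np.random.default_rng(seed)

    if unit == "site":
        null = np.empty(B, dtype=np.int64)
        for b in range(B):
            idx = rng.choice(N, size=K, replace=False)
            null[b] = int(sig[idx].sum())
    elif unit == "gene":
        if site_genes is None:
            raise ValueError("unit='gene' requires site_genes")
        null = _gene_label_null(sig, obe, site_genes, B, rng)
    else:
        raise ValueError(f"unknown permutation unit: {unit!r}")

    p_perm = (1 + int((null >= k_obs).sum())) / (B + 1)
    table = EnrichmentTable(N, K, n, k_obs)
    return EnrichmentResult(
        table=table,
        p_hypergeometric=hypergeometric_test(table),
        p_permutation=float(p_perm),
        n_permutations=B,
        seed=seed,
        unit=unit,
        null_overlap_mean=float(null.mean()),
        null_overlap_sd=float(null.std(ddof=1)) if B > 1 else 0.0,
    )


def _gene_label_null(sig, obe, site_genes, B, rng):
    """Null overlaps when obesity labels are permuted over genes."""
    gene_lists = [s.split(",") if s else [] for s in site_genes]
    genes = sorted({g for lst in gene_lists for g in lst if g})
    gene_idx = {g: i for i, g in enumerate(genes)}
    obesity_genes = {
        g for lst, f in zip(gene_lists, obe) if f for g in lst
    }
    n_obesity_genes = sum(1 for g in genes if g in obesity_genes)
    pair_site = np.array(
        [i for i, lst in enumerate(gene_lists) for g in lst if g], dtype=np.int64
    )
    pair_gene = np.array(
        [gene_idx[g] for lst in gene_lists for g in lst if g], dtype=np.int64
    )
    sig_idx = np.asarray(sig, dtype=bool)
    null = np.empty(B, dtype=np.int64)
    n_sites = len(gene_lists)
    for b in range(B):
        chosen = rng.choice(len(genes), size=n_obesity_genes, replace=False)
        gflag = np.zeros(len(genes), dtype=bool)
        gflag[chosen] = True
        site_hit = np.zeros(n_sites, dtype=bool)
        site_hit[pair_site[gflag[pair_gene]]] = True
        null[b] = int((site_hit & sig_idx).sum())
    return null


def enrich(
    results: pd.DataFrame,
    annotations: pd.DataFrame,
    alpha_site: float = 0.05,
    B: int = 10_000,
    seed: int = 0,
    unit: str = "site",
) -> EnrichmentResult:
    """Full enrichment analysis from per-site results and annotations."""
    merged = results.join(annotations, how="inner")
    pool = merged[merged["converged"] & merged["intragenic"]]
    if pool.empty:
        raise ValueError("no converged intragenic sites; cannot run enrichment")
    sig = (pool["p_value"] < alpha_site).to_numpy()
    obe = pool["obesity_flag"].to_numpy(dtype=bool)
    return permutation_test(
        sig,
        obe,
        B=B,
        seed=seed,
        unit=unit,
        site_genes=pool["gene_symbols"].tolist() if unit == "gene" else None,
    )


def format_report(result: EnrichmentResult) -> str:
    """Human-readable enrichment summary."""
    t = result.table
    cells = t.cells
    lines = [
        "Obesity gene-set enrichment among converged intragenic CpG sites",
        f"  universe N = {t.n_total_intragenic:,}  "
        f"obesity-gene sites K = {t.n_obesity_sites:,}  "
        f"significant (p < {t.alpha_site:g}) n = {t.n_significant:,}",
        f"  2x2 cells (sig&obesity, sig&bg, nonsig&obesity, nonsig&bg): "
        f"{cells[0]:,} / {cells[1]:,} / {cells[2]:,} / {cells[3]:,}",
        f"  significant fraction: obesity {100 * t.significant_fraction_obesity:.1f}%"
        f" vs background {100 * t.significant_fraction_background:.1f}%",
        f"  hypergeometric p = {result.p_hypergeometric:.3g}",
        f"  permutation p = {result.p_permutation:.3g} "
        f"(B = {result.n_permutations:,}, unit = {result.unit}, "
        f"seed = {result.seed})",
        f"  null overlap mean (sd) = {result.null_overlap_mean:.2f} "
        f"({result.null_overlap_sd:.2f}); observed k = {t.n_overlap}",
    ]
    return "\n".join(lines)
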