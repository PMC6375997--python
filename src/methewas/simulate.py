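"""Synthetic RRBS methylation cohorts with a known ground truth.

The generator emulates the structure the downstream analysis assumes: a
cohort of adolescents (default 263) with age, sex, race and assay-batch
covariates; a single linear pseudo-genome partitioned into non-overlapping
genes and intergenic gaps; CpG sites scattered uniformly along it; per-site
baseline methylation from a bimodal beta mixture (most CpGs are nearly un-
or fully methylated); negative-binomial read depth with cells below 10x
unusable; and a continuous BMI-percentile outcome that responds to
methylation at a configurable list of effect sites, expressed per 10%
methylation.

The phenotype couples to the *measured* methylation level at QC-passing
cells (and to the latent methylation probability where the cell is
unusable), so an injected per-10% coefficient is exactly the estimand of
the downstream per-site regression. Missingness is driven purely by read
depth, independent of the outcome (missing at random), so the
missingness-bias check has a true null.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, obesity_gene_set_path
from .coverage import MethylationMatrix, SiteCounts, write_coverage_file


class InvalidConfigError(ValueError):
    """A simulation configuration violates its invariants."""


#: default injected effects: per-10% methylation effects on BMI percentile,
#: concentrated on obesity-set genes at the magnitudes of the well-measured
#: published top sites (several genes carry multiple affected CpGs).
DEFAULT_EFFECT_SITES: tuple[tuple[str, float], ...] = (
    ("SIM1", 7.2),
    ("SIM1", 3.8),
    ("CPE", 4.0),
    ("CPE", 4.0),
    ("RMST", -4.4),
    ("ADRB3", 3.7),
    ("GLUL", 7.9),
    ("GLUL", 8.0),
    ("GLUL", 7.9),
    ("GLUL", 7.8),
    ("CYP2E1", 4.5),
    ("ICAM1", -5.0),
    ("FTO", 5.0),
    ("PACS1", 5.0),
    ("LEPR", 4.0),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 263
    n_sites: int = 20_000
    n_genes: int = 1_200
    n_obesity_genes: int = 50
    frac_intergenic: float = 0.38
    effect_sites: tuple[tuple[str, float], ...] = DEFAULT_EFFECT_SITES
    coverage_mean: float = 30.0
    coverage_dispersion: float = 2.0  # NB size; inf -> Poisson depth
    site_coverage_sigma: float = 0.6  # lognormal spread of per-site mean depth
    missing_target: float = 0.19  # expected sub-10x cell fraction (defaults)
    noise_sd: float = 25.0  # residual SD of BMI percentile
    seed: int = 0
    # cohort demographics (published descriptive statistics)
    age_mean: float = 16.7
    age_sd: float = 2.2
    age_range: tuple[float, float] = (12.0, 23.0)
    p_male: float = 0.559
    p_white: float = 0.787
    n_batches: int = 4
    # outcome model
    bmi_baseline: float = 70.9  # mean 65.4 after the race term at p_white
    age_coef: float = 0.0
    male_coef: float = 0.0
    white_coef: float = -7.0  # white participants have lower BMI percentile
    bmi_clamp: tuple[float, float] = (0.5, 99.5)
    # methylation marginal structure
    mixture_weights: tuple[float, float, float] = (0.45, 0.45, 0.10)
    subject_concentration: float = 40.0  # beta concentration around site mean
    effect_concentration: float = 15.0  # looser at effect sites (more spread)
    batch_shift_sd: float = 0.0  # additive per-batch shift on percent scale
    gene_length: int = 2_000
    min_coverage: int = 10

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_sites": self.n_sites,
            "n_genes": self.n_genes,
            "n_obesity_genes": self.n_obesity_genes,
            "n_batches": self.n_batches,
            "gene_length": self.gene_length,
        }
        for name, value in counts.items():
            if value <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {value}")
        for name, value in {
            "frac_intergenic": self.frac_intergenic,
            "missing_target": self.missing_target,
            "p_male": self.p_male,
            "p_white": self.p_white,
        }.items():
            if not 0.0 <= value <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {value}")
        if self.n_obesity_genes > self.n_genes:
            raise InvalidConfigError("n_obesity_genes cannot exceed n_genes")
        if self.noise_sd < 0 or self.coverage_mean <= 0:
            raise InvalidConfigError("noise_sd >= 0 and coverage_mean > 0 required")
        if not self.coverage_dispersion > 0:
            raise InvalidConfigError("coverage_dispersion must be positive")
        if abs(sum(self.mixture_weights) - 1.0) > 1e-9:
            raise InvalidConfigError("mixture_weights must sum to 1")


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort plus its generative ground truth."""

    config: SimulationConfig
    sample_table: pd.DataFrame
    gene_model: GeneModel
    matrix: MethylationMatrix  # QC-masked percent (<10x missing) + coverage
    count_methylated: pd.DataFrame
    count_unmethylated: pd.DataFrame
    truth: pd.DataFrame  # chromosome, position, gene, effect_per_10pct

    def coverage_records(self, subject: str) -> list[SiteCounts]:
        """Per-subject site records for cells with at least one read."""
        m = self.count_methylated[subject]
        u = self.count_unmethylated[subject]
        keep = (m + u) > 0
        return [
            SiteCounts(chrom, int(pos), int(mi), int(ui))
            for (chrom, pos), mi, ui in zip(m.index[keep], m[keep], u[keep])
        ]


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one independent, reproducible stream per generation stage
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stage]))


def simulate_subjects(config: SimulationConfig) -> pd.DataFrame:
    """Draw the covariate table and the pre-methylation outcome.

    Age is truncated normal; sex, race are Bernoulli at the published
    frequencies; batches are assigned round-robin. ``bmi_percentile`` here
    is baseline + covariate terms + noise (clamped); the methylation effect
    terms are added by :func:`simulate_methylation`, which keeps the
    unclamped latent value in the ``_bmi_latent`` column until then.
    """
    config.validate()
    rng = _rng(config, stage=0)
    n = config.n_subjects
    lo, hi = config.age_range
    age = np.empty(n)
    filled = 0
    while filled < n:  # rejection sampling of the truncated normal
        draw = rng.normal(config.age_mean, config.age_sd, size=2 * (n - filled))
        draw = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        age[filled : filled + draw.size] = draw
        filled += draw.size
    male = rng.random(n) < config.p_male
    white = rng.random(n) < config.p_white
    batch = np.arange(n) % config.n_batches + 1
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else 0.0
    latent = (
        config.bmi_baseline
        + config.age_coef * (age - config.age_mean)
        + config.male_coef * male
        + config.white_coef * white
        + noise
    )
    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "age": np.round(age, 2),
            "sex": np.where(male, "male", "female"),
            "race": np.where(white, "white", "other"),
            "batch": batch,
            "bmi_percentile": np.clip(latent, *config.bmi_clamp),
            "_bmi_latent": latent,
        }
    )
    return table


def _build_genome(config: SimulationConfig, rng: np.random.Generator):
    """Lay out genes and gaps on one linear chromosome; returns the gene
    model and the genome length."""
    genic_total = config.n_genes * config.gene_length
    genome_length = int(round(genic_total / (1.0 - config.frac_intergenic)))
    gap = (genome_length - genic_total) / (config.n_genes + 1)
    starts = np.round(
        gap + np.arange(config.n_genes) * (config.gene_length + gap)
    ).astype(int) + 1
    ends = starts + config.gene_length - 1

    fixture_symbols = pd.read_csv(obesity_gene_set_path(), sep="\t")[
        "gene_symbol"
    ].tolist()
    # genes carrying injected effects must be on the genome
    effect_genes = [g for g, _ in config.effect_sites]
    wanted = list(dict.fromkeys(effect_genes))
    if len(wanted) > config.n_obesity_genes:
        raise InvalidConfigError(
            "more distinct effect genes than obesity genes on the genome"
        )
    obesity_symbols = wanted + [
        g for g in fixture_symbols if g not in wanted
    ][: config.n_obesity_genes - len(wanted)]
    slots = np.sort(
        rng.choice(config.n_genes, size=config.n_obesity_genes, replace=False)
    )
    names = [f"GENE{i + 1:04d}" for i in range(config.n_genes)]
    for slot, symbol in zip(slots, obesity_symbols):
        names[slot] = symbol
    model = GeneModel(
        pd.DataFrame(
            {
                "gene_symbol": names,
                "chromosome": "chr1",
                "start": starts,
                "end": ends,
            }
        )
    )
    return model, genome_length


def _place_sites(config: SimulationConfig, model: GeneModel, genome_length: int, rng):
    """Uniform site positions plus one dedicated site per injected effect."""
    n_effects = len(config.effect_sites)
    if n_effects > config.n_sites:
        raise InvalidConfigError("more effect sites than total sites")
    gene_rows = model.table.set_index("gene_symbol")
    effect_positions = []
    per_gene_counter: dict[str, int] = {}
    for gene, _ in config.effect_sites:
        if gene not in gene_rows.index:
            raise InvalidConfigError(f"effect gene {gene!r} not on the genome")
        idx = per_gene_counter.get(gene, 0)
        per_gene_counter[gene] = idx + 1
        row = gene_rows.loc[gene]
        span = int(row.end) - int(row.start)
        # spread multiple effect sites across the gene body
        pos = int(row.start) + (span * (2 * idx + 1)) // (2 * max(per_gene_counter[gene], 4))
        effect_positions.append(pos)
    background = rng.choice(
        genome_length, size=config.n_sites - n_effects, replace=False
    ) + 1
    taken = set(effect_positions)
    background = [p for p in background if p not in taken]
    positions = np.array(sorted(taken | set(background)), dtype=int)
    return positions, np.array(effect_positions, dtype=int)


def simulate_methylation(
    config: SimulationConfig, samples: pd.DataFrame
) -> SyntheticCohort:
    """Draw the genome, methylation counts and final outcome.

    Per-site baseline methylation comes from a three-component beta mixture
    (low / high / intermediate); subject-level methylation probabilities are
    beta-distributed around the site baseline; read depth is negative
    binomial around a lognormally varying per-site mean; methylated counts
    are binomial. Cells under ``min_coverage`` reads are masked missing in
    the returned matrix. Injected effects then feed the outcome.
    """
    config.validate()
    rng = _rng(config, stage=1)
    model, genome_length = _build_genome(config, rng)
    positions, effect_positions = _place_sites(config, model, genome_length, rng)
    n_sites, n_subj = len(positions), config.n_subjects

    # site baseline methylation probability: bimodal beta mixture
    comp = rng.choice(3, size=n_sites, p=list(config.mixture_weights))
    pi = np.empty(n_sites)
    pi[comp == 0] = rng.beta(1.5, 15.0, size=int((comp == 0).sum()))  # low
    pi[comp == 1] = rng.beta(15.0, 1.5, size=int((comp == 1).sum()))  # high
    pi[comp == 2] = rng.beta(5.0, 5.0, size=int((comp == 2).sum()))  # mid

    pos_to_row = {int(p): i for i, p in enumerate(positions)}
    effect_rows = np.array([pos_to_row[int(p)] for p in effect_positions], int)
    # effect sites get intermediate baselines so methylation varies enough
    # across subjects for the effect to be identifiable
    pi[effect_rows] = rng.uniform(0.3, 0.7, size=effect_rows.size)

    phi = np.full(n_sites, config.subject_concentration)
    phi[effect_rows] = config.effect_concentration
    pi_c = np.clip(pi, 1e-6, 1.0 - 1e-6)
    prob = rng.beta(
        np.outer(pi_c * phi, np.ones(n_subj)),
        np.outer((1.0 - pi_c) * phi, np.ones(n_subj)),
    )
    if config.batch_shift_sd > 0:
        shifts = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches)
        batch_idx = samples["batch"].to_numpy(int) - 1
        prob = np.clip(prob + shifts[batch_idx][None, :] / 100.0, 0.0, 1.0)

    # read depth: NB around a lognormally varying per-site mean
    site_mu = config.coverage_mean * rng.lognormal(
        0.0, config.site_coverage_sigma, size=n_sites
    )
    mu = np.broadcast_to(site_mu[:, None], (n_sites, n_subj))
    r = config.coverage_dispersion
    if np.isinf(r):
        depth = rng.poisson(mu)
    else:
        depth = rng.negative_binomial(r, r / (r + mu))
    n_meth = rng.binomial(depth, prob)
    n_unmeth = depth - n_meth

    index = pd.MultiIndex.from_arrays(
        [np.repeat("chr1", n_sites), positions], names=["chromosome", "position"]
    )
    subjects = samples["subject_id"].astype(str).tolist()
    with np.errstate(invalid="ignore", divide="ignore"):
        percent_raw = 100.0 * n_meth / depth
    usable = depth >= config.min_coverage
    percent = pd.DataFrame(
        np.where(usable, percent_raw, np.nan), index=index, columns=subjects
    )
    matrix = MethylationMatrix(
        percent=percent,
        coverage=pd.DataFrame(depth, index=index, columns=subjects),
    )

    # outcome: add the injected effect terms to the latent outcome.
    # QC-passing cells contribute their measured percent; unusable cells
    # contribute the latent probability (MAR: depth is independent of BMI).
    latent = samples["_bmi_latent"].to_numpy(float).copy()
    for (gene, effect), row in zip(config.effect_sites, effect_rows):
        x = np.where(usable[row], percent_raw[row], 100.0 * prob[row])
        # center on the site's expected level: leaves the slope (the
        # estimand) untouched but keeps the outcome mean at baseline
        latent += effect * (x - 100.0 * pi_c[row]) / 10.0
    final = samples.drop(columns=["_bmi_latent"]).copy()
    final["bmi_percentile"] = np.clip(latent, *config.bmi_clamp)

    truth = pd.DataFrame(
        {
            "chromosome": "chr1",
            "position": effect_positions,
            "gene": [g for g, _ in config.effect_sites],
            "effect_per_10pct": [e for _, e in config.effect_sites],
        }
    )
    return SyntheticCohort(
        config=config,
        sample_table=final,
        gene_model=model,
        matrix=matrix,
        count_methylated=pd.DataFrame(n_meth, index=index, columns=subjects),
        count_unmethylated=pd.DataFrame(n_unmeth, index=index, columns=subjects),
        truth=truth,
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Convenience: subjects then methylation, one call."""
    return simulate_methylation(config, simulate_subjects(config))


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort as analysis-ready files; returns the manifest.

    One coverage file per subject (cells with >= 1 read), the gene model as
    BED, the sample table, the full packaged gene-set TSV, and the truth
    table. The manifest (also stored as ``manifest.json``) lists every file
    with its row count. Byte-identical across runs with the same seed.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, int] = {}

    for subject in cohort.sample_table["subject_id"].astype(str):
        name = f"{subject}.cov.tsv"
        n = write_coverage_file(cohort.coverage_records(subject), directory / name)
        files[name] = n

    cohort.gene_model.to_bed(directory / "genes.bed")
    files["genes.bed"] = len(cohort.gene_model.table)

    samples_out = cohort.sample_table[
        ["subject_id", "age", "sex", "race", "batch", "bmi_percentile"]
    ].copy()
    samples_out["bmi_percentile"] = samples_out["bmi_percentile"].map(
        lambda v: f"{v:.4f}"
    )
    samples_out.to_csv(directory / "samples.tsv", sep="\t", index=False)
    files["samples.tsv"] = len(samples_out)

    gene_set = pd.read_csv(obesity_gene_set_path(), sep="\t")
    gene_set.to_csv(directory / "gene_set.tsv", sep="\t", index=False)
    files["gene_set.tsv"] = len(gene_set)

    cohort.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)
    files["truth.tsv"] = len(cohort.truth)

    manifest = {
        "seed": cohort.config.seed,
        "n_subjects": cohort.config.n_subjects,
        "n_sites": cohort.config.n_sites,
        "files": dict(sorted(files.items())),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def cohort_checksum(directory: str | Path) -> str:
    """SHA-256 over all written cohort files (name + content)."""
    digest = hashlib.sha256()
    for path in sorted(Path(directory).iterdir()):
        if path.is_file():
            digest.update(path.name.encode())
            digest.update(path.read_bytes())
    return digest.hexdigest()
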