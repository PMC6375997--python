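"""Gene annotation of CpG sites and the a-priori obesity gene set.

A site is *intragenic* when its position falls inside the annotated span of
at least one gene (1-based inclusive bounds on the same chromosome), and is
assigned to every such gene. The obesity gene set is the list of genes
retrieved from a gene-disease association database at reliability score
>= 0.20; it ships with the package as a 50-gene TSV fixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class GeneModel:
    """Gene spans, 1-based inclusive. A symbol may span several intervals."""

    table: pd.DataFrame  # columns: gene_symbol, chromosome, start, end

    def __post_init__(self) -> None:
        required = {"gene_symbol", "chromosome", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"gene model missing columns: {sorted(missing)}")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene model has intervals with start > end")

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneModel":
        """Load a BED file (0-based, half-open); name column = gene symbol."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            usecols=[0, 1, 2, 3],
            names=["chromosome", "start", "end", "gene_symbol"],
        )
        df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
        df["end"] = df["end"].astype(int)
        return cls(df[["gene_symbol", "chromosome", "start", "end"]])

    def to_bed(self, path: str | Path) -> None:
        out = self.table.copy()
        out["bed_start"] = out["start"] - 1
        out["score"] = 0
        out["strand"] = "+"
        out[
            ["chromosome", "bed_start", "end", "gene_symbol", "score", "strand"]
        ].to_csv(path, sep="\t", header=False, index=False)


@dataclass(frozen=True)
class GeneSet:
    """Gene -> reliability score map with a selection threshold.

    ``selected`` holds the case-normalized symbols with score >= threshold.
    """

    scores: dict[str, float]
    threshold: float = 0.20
    selected: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        bad = {g: s for g, s in self.scores.items() if not 0.0 <= s <= 1.0}
        if bad:
            raise ValueError(f"reliability scores outside [0, 1]: {bad}")
        object.__setattr__(
            self,
            "selected",
            frozenset(
                g.upper() for g, s in self.scores.items() if s >= self.threshold
            ),
        )

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.selected

    def __len__(self) -> int:
        return len(self.selected)


def load_gene_set(path: str | Path, threshold: float = 0.20) -> GeneSet:
    """Load a two-column ``gene_symbol<TAB>reliability_score`` TSV and keep
    genes at or above the threshold (strict >= ; a score of exactly the
    threshold is retained)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError("gene set file must have exactly two columns")
    df.columns = ["gene_symbol", "reliability_score"]
    return GeneSet(
        scores=dict(
            zip(df["gene_symbol"].astype(str), df["reliability_score"].astype(float))
        ),
        threshold=threshold,
    )


def obesity_gene_set_path() -> Path:
    """Path of the packaged 50-gene obesity set fixture."""
    return Path(
        resources.files("methewas").joinpath("data/disgenet_obesity_top50.tsv")
    )


def load_obesity_gene_set(threshold: float = 0.20) -> GeneSet:
    return load_gene_set(obesity_gene_set_path(), threshold=threshold)


def annotate_sites(
    sites: Iterable[tuple[str, int]], model: GeneModel
) -> pd.DataFrame:
    """Assign each (chromosome, position) site to containing genes.

    Returns a frame indexed by (chromosome, position) with columns
    ``gene_symbols`` (comma-joined, sorted; empty string if none) and
    ``intragenic``. Sites on chromosomes absent from the model are
    intergenic, not errors. Containment is inclusive at both gene bounds.
    """
    trees: dict[str, IntervalTree] = {}
    for row in model.table.itertuples(index=False):
        tree = trees.setdefault(row.chromosome, IntervalTree())
        # +1: intervaltree is half-open, gene spans are inclusive
        tree.addi(row.start, row.end + 1, row.gene_symbol)

    index, symbols = [], []
    for chrom, pos in sites:
        index.append((chrom, pos))
        tree = trees.get(chrom)
        hits = sorted({iv.data for iv in tree[pos]}) if tree is not None else []
        symbols.append(",".join(hits))
    out = pd.DataFrame(
        {"gene_symbols": symbols},
        index=pd.MultiIndex.from_tuples(index, names=["chromosome", "position"]),
    )
    out["intragenic"] = out["gene_symbols"] != ""
    return out


def flag_obesity_sites(annotations: pd.DataFrame, gene_set: GeneSet) -> pd.DataFrame:
    """Add ``obesity_flag``: true iff any assigned gene is in the selected
    set (case-insensitive). Intergenic sites are never flagged."""
    out = annotations.copy()
    out["obesity_flag"] = [
        any(g in gene_set for g in syms.split(",")) if syms else False
        for syms in out["gene_symbols"]
    ]
    return out


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    annotations.reset_index().to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    df["gene_symbols"] = df["gene_symbols"].astype(str)
    for col in ("intragenic", "obesity_flag"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"True": True, "False": False})
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df.set_index(["chromosome", "position"])
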