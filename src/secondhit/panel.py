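"""Targeted-panel designs: ordered capture intervals with gene labels.

A panel is a BED-style table of capture intervals (0-based, half-open
internally; reports are 1-based inclusive). Each interval carries the gene
symbol, a region class (``coding-exon`` for an exon bait, ``whole-gene-tile``
for one tile of a contiguously tiled gene body) and a positive relative
capture efficiency used by the coverage simulator.

The miniature default panel emulates the structure of a clinical IRD design:
three genes tiled across their whole genomic extent (so CNV breakpoints fall
inside covered sequence) plus coding exons of further panel genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_COLUMNS = ["chrom", "start", "end", "gene", "region_class", "efficiency"]

REGION_CLASSES = ("coding-exon", "whole-gene-tile")


@dataclass
class PanelDesign:
    """Ordered, non-overlapping capture intervals over a reference build."""

    intervals: pd.DataFrame
    build: str = "hg19"

    def __post_init__(self):
        df = self.intervals
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"panel table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("panel must contain at least one interval")
        if (df["end"] <= df["start"]).any():
            raise ValueError("every interval needs end > start")
        if (df["efficiency"] <= 0).any():
            raise ValueError("capture efficiencies must be positive")
        bad = ~df["region_class"].isin(REGION_CLASSES)
        if bad.any():
            raise ValueError(
                f"unknown region class: {sorted(df.loc[bad, 'region_class'].unique())}"
            )
        for chrom, sub in df.groupby("chrom", sort=False):
            if not sub["start"].is_monotonic_increasing:
                raise ValueError(f"intervals on {chrom} are not sorted")
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError(f"intervals on {chrom} overlap")
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def lengths(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()

    def overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices of intervals overlapping [start, end) on ``chrom``."""
        df = self.intervals
        mask = (df["chrom"] == chrom) & (df["start"] < end) & (df["end"] > start)
        return np.flatnonzero(mask.to_numpy())

    def to_bed(self, path) -> None:
        self.intervals[_COLUMNS].to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def from_bed(cls, path, build: str = "hg19") -> "PanelDesign":
        df = pd.read_csv(
            path, sep="\t", header=None, names=_COLUMNS,
            dtype={"chrom": str, "start": int, "end": int,
                   "gene": str, "region_class": str, "efficiency": float},
        )
        return cls(df, build=build)


def whole_gene_tiles(
    chrom: str, start: int, end: int, gene: str,
    tile: int = 100, efficiency: float = 1.0,
) -> pd.DataFrame:
    """Tile [start, end) into fixed-size whole-gene-tile intervals."""
    edges = np.arange(start, end, tile)
    ends = np.minimum(edges + tile, end)
    return pd.DataFrame(
        {"chrom": chrom, "start": edges, "end": ends, "gene": gene,
         "region_class": "whole-gene-tile", "efficiency": efficiency}
    )


def default_panel(seed: int = 0) -> PanelDesign:
    """Miniature stand-in panel built programmatically.

    Whole-gene tiles (100 bp) over shortened USH2A/ABCA4/CEP290 stand-in
    regions plus a few dozen coding exons of other panel genes, with mildly
    heterogeneous capture efficiencies. Coordinates are synthetic; the real
    1,239-region clinical design is not public.
    """
    rng = np.random.default_rng(seed)
    parts = [
        whole_gene_tiles("chr1", 94_458_000, 94_464_000, "ABCA4"),
        whole_gene_tiles("chr1", 215_900_000, 215_910_000, "USH2A"),
        whole_gene_tiles("chr12", 88_442_000, 88_448_000, "CEP290"),
    ]
    exon_genes = ["CNGB3", "LRAT", "FSCN2", "CRB1", "RPE65", "EYS", "PDE6B", "RHO"]
    exon_rows = []
    pos = 5_000_000
    for i, gene in enumerate(exon_genes):
        chrom = f"chr{2 + i}"
        pos = 5_000_000
        for _ in range(6):
            length = int(rng.integers(120, 300))
            exon_rows.append((chrom, pos, pos + length, gene, "coding-exon", 1.0))
            pos += length + int(rng.integers(2_000, 20_000))
    parts.append(pd.DataFrame(exon_rows, columns=_COLUMNS))
    df = pd.concat(parts, ignore_index=True)
    # capture efficiency varies bait to bait; keep it positive and mild
    df["efficiency"] = np.exp(rng.normal(0.0, 0.15, size=len(df)))
    return PanelDesign(df)
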