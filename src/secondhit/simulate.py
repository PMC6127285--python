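"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates what a targeted capture batch looks like from the
point of view of the downstream method:

* per-interval read counts that are Poisson around an expectation of
  ``library_size x capture_efficiency x interval_length x copy_number/2``,
  with lognormal per-sample library-size variation;
* embedded deletion/duplication events at copy number 0, 1 or 3;
* binomial allele sampling at heterozygous SNPs — balanced (p = 1/2) in a
  diploid region, and 2-of-3 copies for the major haplotype (p = 2/3) in a
  tandem three-copy region;
* variant tables in which common polymorphisms dominate and only a
  configurable fraction survives the rare-frequency screen;
* base-resolution coverage tracks with a copy-number step at specified
  breakpoints, for breakpoint-refinement inputs.

Everything is driven by ``numpy.random.default_rng``: a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cnv import CoverageMatrix, CoverageTrack
from .panel import PanelDesign
from .variants import MAF_DATABASES, VariantRecord

#: nominal read length used to convert per-base depth into read counts
READ_LENGTH = 100

SUPPORTED_COPY_NUMBERS = (0, 1, 3)


@dataclass(frozen=True)
class CnvEvent:
    """A deletion/duplication embedded in one simulated sample."""

    sample: str
    chrom: str
    start: int  # 0-based, half-open span
    end: int
    copy_number: int

    def __post_init__(self):
        if self.copy_number not in SUPPORTED_COPY_NUMBERS:
            raise ValueError(
                f"copy_number must be one of {SUPPORTED_COPY_NUMBERS}, "
                f"got {self.copy_number}"
            )
        if self.end <= self.start:
            raise ValueError("event span needs end > start")


@dataclass
class SimulationConfig:
    """Batch-level knobs for :func:`simulate_coverage`."""

    n_samples: int = 6
    mean_depth: float = 200.0
    library_size_sd: float = 0.2
    cnv_events: Sequence[CnvEvent] = field(default_factory=tuple)
    snp_density: float = 1.0  # het SNPs per kb, used by track-level helpers
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 3:
            raise ValueError(
                "the cross-sample ratio method needs a batch of >= 3 samples"
            )
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.library_size_sd < 0:
            raise ValueError("library_size_sd must be non-negative")

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


def _copy_number_weights(design: PanelDesign, config: SimulationConfig) -> np.ndarray:
    """Per (sample, interval) dosage factor copy_number/2, default 1."""
    weights = np.ones((config.n_samples, len(design)))
    names = config.sample_names
    for event in config.cnv_events:
        if event.sample not in names:
            raise ValueError(f"cnv_event names unknown sample {event.sample!r}")
        hit = design.overlapping(event.chrom, event.start, event.end)
        if hit.size == 0:
            raise ValueError(
                f"cnv_event span {event.chrom}:{event.start}-{event.end} "
                "lies outside the panel"
            )
        s = names.index(event.sample)
        iv = design.intervals
        for j in hit:
            length = iv.at[j, "end"] - iv.at[j, "start"]
            overlap = min(event.end, iv.at[j, "end"]) - max(event.start, iv.at[j, "start"])
            frac = overlap / length
            # partial overlap dilutes the dosage step proportionally
            weights[s, j] *= 1.0 + (event.copy_number / 2.0 - 1.0) * frac
    return weights


def simulate_coverage(
    design: PanelDesign, config: SimulationConfig, batch_id: str = "batch1"
) -> CoverageMatrix:
    """Draw a per-interval read-count matrix for one sequencing batch.

    Expected diploid count for interval *j* in sample *i* is
    ``lib_i * mean_depth * efficiency_j * length_j / READ_LENGTH``, where
    ``lib_i`` is a lognormal per-sample factor with unit mean; CNV events
    scale the expectation by ``copy_number / 2``. Counts are Poisson.
    """
    rng = np.random.default_rng(config.seed)
    sd = config.library_size_sd
    lib = np.exp(rng.normal(0.0, sd, size=config.n_samples))
    if sd > 0:
        lib /= np.exp(sd**2 / 2.0)  # unit-mean lognormal
    base = (
        config.mean_depth
        * design.intervals["efficiency"].to_numpy()
        * design.lengths
        / READ_LENGTH
    )
    expectation = lib[:, None] * base[None, :] * _copy_number_weights(design, config)
    counts = rng.poisson(expectation)
    matrix = pd.DataFrame(
        counts.T, columns=config.sample_names, index=design.intervals.index
    )
    return CoverageMatrix(
        intervals=design.intervals,
        counts=matrix,
        batch_id=batch_id,
        library_sizes=pd.Series(expectation.sum(axis=1), index=config.sample_names),
    )


def simulate_allele_depths(
    region_copy_number: int,
    n_snps: int,
    total_depth: int,
    seed: int = 0,
    chrom: str = "chr1",
    start: int = 1,
    spacing: int = 500,
) -> pd.DataFrame:
    """Sample read depths at heterozygous SNPs inside a 2- or 3-copy region.

    In a diploid region both alleles carry one copy, so alternate reads are
    Binomial(depth, 1/2). In a tandem three-copy region the duplicated
    haplotype carries 2 of 3 copies, so the major allele draws
    Binomial(depth, 2/3) — the allele-ratio shift from ~50:50 to ~67:33
    that corroborates a duplication.
    """
    if region_copy_number not in (2, 3):
        raise ValueError(
            f"region_copy_number must be 2 or 3, got {region_copy_number}"
        )
    if total_depth <= 0:
        raise ValueError("total_depth must be positive")
    rng = np.random.default_rng(seed)
    p_major = 0.5 if region_copy_number == 2 else 2.0 / 3.0
    major = rng.binomial(total_depth, p_major, size=n_snps)
    # which physical allele (ref/alt) is the duplicated one is random
    major_is_alt = rng.random(n_snps) < 0.5
    alt = np.where(major_is_alt, major, total_depth - major)
    pos = start + spacing * np.arange(n_snps)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref_depth": total_depth - alt,
            "alt_depth": alt,
        }
    )


_SIM_GENES = ("USH2A", "ABCA4", "CEP290", "CRB1", "EYS", "RPE65", "CNGB3", "PDE6B")
_SIM_CONSEQUENCES = (
    "missense", "synonymous-splice", "intronic-splicing", "deep-intronic",
    "nonsense", "frameshift", "other",
)
_SIM_CONSEQ_P = (0.45, 0.05, 0.08, 0.2, 0.03, 0.04, 0.15)


def simulate_variant_table(
    n_variants: int,
    rare_fraction: float,
    seed: int = 0,
    maf_threshold: float = 0.015,
) -> list[VariantRecord]:
    """Draw an annotated variant table with a realistic MAF spectrum.

    Approximately ``rare_fraction`` of the records have a maximum database
    MAF below ``maf_threshold`` (or are absent from every database), so the
    rare-frequency screen retains about that fraction. DP and FS are
    populated so records are QC-evaluable.
    """
    if not 0.0 <= rare_fraction <= 1.0:
        raise ValueError("rare_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[VariantRecord] = []
    bases = np.array(list("ACGT"))
    for i in range(n_variants):
        rare = rng.random() < rare_fraction
        maf: dict[str, float] = {}
        if rare:
            if rng.random() < 0.3:
                pass  # novel: observed in no database
            else:
                for db in MAF_DATABASES:
                    if rng.random() < 0.6:
                        # log-uniform below the screen threshold
                        maf[db] = float(
                            10 ** rng.uniform(-5, np.log10(maf_threshold * 0.999))
                        )
        else:
            # common polymorphism: at least one database reports it as common
            n_common = 1 + rng.binomial(len(MAF_DATABASES) - 1, 0.8)
            dbs = rng.choice(len(MAF_DATABASES), size=n_common, replace=False)
            common_f = float(rng.uniform(maf_threshold, 0.5))
            for k in dbs:
                maf[MAF_DATABASES[k]] = float(
                    min(0.5, common_f * rng.uniform(0.9, 1.1) + maf_threshold * 1e-3)
                )
        ref, alt = rng.choice(4, size=2, replace=False)
        records.append(
            VariantRecord(
                variant_id=f"sim{i + 1}",
                chrom="chr1",
                pos=1_000_000 + 50 * i,
                ref=str(bases[ref]),
                alt=str(bases[alt]),
                gene=str(rng.choice(_SIM_GENES)),
                consequence=str(rng.choice(_SIM_CONSEQUENCES, p=_SIM_CONSEQ_P)),
                zygosity="hom" if rng.random() < 0.1 else "het",
                dp=int(rng.poisson(200)),
                fs=float(round(rng.exponential(5.0), 3)),
                maf=maf,
            )
        )
    return records


def simulate_gene_cnv_batch(
    chrom: str,
    region_start: int,
    region_end: int,
    gene: str,
    event_start: int,
    event_end: int,
    copy_number: int,
    carrier: str = "CASE",
    n_samples: int = 6,
    mean_depth: float = 800.0,
    tile: int = 1000,
    ballast_bp: int = 1_100_000,
    seed: int = 0,
):
    """A whole-gene CNV scenario: interval batch plus base-resolution tracks.

    Builds a panel of ``tile``-sized whole-gene tiles over the region plus
    ballast coding-exon intervals on another chromosome (so the tiled gene
    is a realistic fraction of total capture, as in a multi-gene clinical
    panel — total-count normalization is only mildly perturbed even by a
    multi-hundred-kb event), simulates a batch with the event embedded in
    ``carrier``, and draws matching per-base tracks for the carrier and a
    diploid reference. ``event_start``/``event_end`` are 1-based inclusive
    first/last affected bases.

    Returns ``(CoverageMatrix, sample_track, reference_track)``.
    """
    from .panel import PanelDesign, whole_gene_tiles

    tiles = whole_gene_tiles(chrom, region_start - 1, region_end, gene, tile=tile)
    n_ballast = max(1, ballast_bp // 1000)
    starts = 1_000_000 + 5_000 * np.arange(n_ballast)
    ballast = pd.DataFrame(
        {"chrom": "chrB", "start": starts, "end": starts + 1_000,
         "gene": "BALLAST", "region_class": "coding-exon", "efficiency": 1.0}
    )
    design = PanelDesign(pd.concat([ballast, tiles], ignore_index=True))
    first = f"S01"
    config = SimulationConfig(
        n_samples=n_samples, mean_depth=mean_depth, library_size_sd=0.1,
        cnv_events=(
            CnvEvent(first, chrom, event_start - 1, event_end, copy_number),
        ),
        seed=seed,
    )
    matrix = simulate_coverage(design, config)
    matrix.counts.columns = [carrier] + config.sample_names[1:]
    sample_track, reference_track = simulate_base_coverage(
        chrom, region_start, region_end, event_start, event_end,
        copy_number=copy_number, mean_depth=mean_depth, seed=seed + 1,
    )
    return matrix, sample_track, reference_track


def simulate_base_coverage(
    chrom: str,
    region_start: int,
    region_end: int,
    event_start: Optional[int] = None,
    event_end: Optional[int] = None,
    copy_number: int = 2,
    mean_depth: float = 800.0,
    seed: int = 0,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Base-resolution depth tracks for a sample and a diploid reference.

    ``event_start``/``event_end`` are 1-based inclusive coordinates of the
    first and last base at altered copy number (HGVS-style, matching how
    breakpoints are reported). Depth is Poisson around
    ``mean_depth * copy_number / 2`` inside the event and ``mean_depth``
    outside; the reference track is Poisson around ``mean_depth``
    throughout. Returns ``(sample_track, reference_track)``.
    """
    if copy_number not in (0, 1, 2, 3):
        raise ValueError("copy_number must be in {0, 1, 2, 3}")
    rng = np.random.default_rng(seed)
    n = region_end - region_start + 1
    expectation = np.full(n, mean_depth, dtype=float)
    if event_start is not None:
        if not (region_start <= event_start <= event_end <= region_end):
            raise ValueError("event span must lie inside the track region")
        lo = event_start - region_start
        hi = event_end - region_start + 1
        expectation[lo:hi] = mean_depth * copy_number / 2.0
    sample = rng.poisson(expectation).astype(float)
    reference = rng.poisson(np.full(n, mean_depth)).astype(float)
    return (
        CoverageTrack(chrom=chrom, start=region_start, depth=sample),
        CoverageTrack(chrom=chrom, start=region_start, depth=reference),
    )
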