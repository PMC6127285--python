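"""Record-level QC and population-frequency screening.

Two filters, applied to annotated variant tables before prioritization:

* **QC** — discard records with coverage below 20X or Phred-scaled strand
  bias (FisherStrand) above 60.0.
* **MAF** — retain only records whose frequency is below 0.015 in *every*
  population database where the variant has been observed (1000G, EVS,
  ExAC, GnomAD, dbSNP, and the Spanish CSVS when populated). Absence from
  a database counts as passing: a novel variant is retained.

Both boundaries are strict, as published: DP = 20 and FS = 60.0 are
retained; a MAF of exactly 0.015 is rejected (the retain rule is
``MAF < 0.015``). The filters are idempotent and commute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .variants import VariantRecord


@dataclass
class ScreenConfig:
    min_dp: int = 20
    max_fs: float = 60.0
    maf_threshold: float = 0.015

    def __post_init__(self):
        if self.min_dp <= 0 or self.max_fs <= 0 or self.maf_threshold <= 0:
            raise ValueError("screen thresholds must be positive")


@dataclass
class Rejection:
    record: VariantRecord
    reason: str


def qc_filter(
    records: Iterable[VariantRecord], config: ScreenConfig | None = None
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Retain records with DP >= min_dp and FS <= max_fs.

    Records missing either QC field are rejected with reason
    ``missing-qc`` rather than silently passed. CNV alleles carry no
    site-level DP/FS and are exempt from this record-level filter.
    """
    config = config or ScreenConfig()
    retained, rejected = [], []
    for r in records:
        if r.is_cnv:
            retained.append(r)
            continue
        if r.dp is None or r.fs is None:
            rejected.append(Rejection(r, "missing-qc"))
        elif r.dp < config.min_dp:
            rejected.append(Rejection(r, "low-depth"))
        elif r.fs > config.max_fs:
            rejected.append(Rejection(r, "strand-bias"))
        else:
            retained.append(r)
    return retained, rejected


def maf_filter(
    records: Iterable[VariantRecord], config: ScreenConfig | None = None
) -> tuple[list[VariantRecord], list[Rejection]]:
    """Retain records rare (< threshold) in every database that saw them."""
    config = config or ScreenConfig()
    retained, rejected = [], []
    for r in records:
        offending = [
            db for db, f in r.maf.items() if f >= config.maf_threshold
        ]
        if offending:
            rejected.append(
                Rejection(r, "common-in-" + ",".join(sorted(offending)))
            )
        else:
            retained.append(r)
    return retained, rejected


def screen(
    records: Iterable[VariantRecord], config: ScreenConfig | None = None
) -> tuple[list[VariantRecord], list[Rejection]]:
    """QC then MAF; returns (retained, all rejections with reasons)."""
    config = config or ScreenConfig()
    kept, rej_qc = qc_filter(records, config)
    kept, rej_maf = maf_filter(kept, config)
    return kept, rej_qc + rej_maf


# ---------------------------------------------------------------------------
# standard-VCF ingestion (optional; cyvcf2-backed)

#: default mapping from record fields to VCF INFO keys
VCF_KEY_TABLE = {
    "gene": "GENE",
    "consequence": "CSQ_CLASS",
    "dp": "DP",
    "fs": "FS",
    "maf": {
        "1000G": "AF_1000G",
        "EVS": "AF_EVS",
        "ExAC": "AF_EXAC",
        "GnomAD": "AF_GNOMAD",
        "dbSNP": "AF_DBSNP",
        "CSVS": "AF_CSVS",
    },
}


def read_vcf(path, key_table: dict | None = None) -> list[VariantRecord]:
    """Read an annotated standard VCF into records.

    Requires the optional ``cyvcf2`` dependency. INFO keys are mapped via
    ``key_table`` (defaults to :data:`VCF_KEY_TABLE`); zygosity comes from
    the first sample's genotype.
    """
    from cyvcf2 import VCF  # optional dependency

    table = key_table or VCF_KEY_TABLE
    records = []
    for v in VCF(str(path)):
        maf = {}
        for db, key in table["maf"].items():
            value = v.INFO.get(key)
            if value is not None:
                maf[db] = float(value)
        zyg = "het"
        if len(v.gt_types) and v.gt_types[0] == 3:  # HOM_ALT
            zyg = "hom"
        dp = v.INFO.get(table["dp"])
        fs = v.INFO.get(table["fs"])
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else None,
                gene=str(v.INFO.get(table["gene"], "NA")),
                consequence=str(v.INFO.get(table["consequence"], "other")),
                zygosity=zyg,
                dp=int(dp) if dp is not None else None,
                fs=float(fs) if fs is not None else None,
                maf=maf,
            )
        )
    return records
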