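"""Annotated small-variant records and VCF-lite TSV input/output.

The pipeline's working representation of a small variant (or a CNV allele
once it has been reduced to an allele of a gene) is :class:`VariantRecord`.
Records carry everything the downstream filters and the prioritization
engine consume: zygosity, calling QC (depth, FisherStrand), a per-database
minor-allele-frequency map, externally produced splice-predictor scores,
database pathogenicity labels, protein-level predictor calls, a novelty
flag and the per-variant segregation outcome.

Tables travel as "VCF-lite" TSV: one row per variant, 1-based positions,
one ``MAF_<DB>`` column per population database (empty = not observed in
that database) and one column pair per splice tool.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, Field, field_validator

Consequence = Literal[
    "missense",
    "nonsense",
    "frameshift",
    "intronic-splicing",
    "synonymous-splice",
    "deep-intronic",
    "cnv-deletion",
    "cnv-duplication",
    "other",
]

Zygosity = Literal["het", "hom"]

DbLabel = Literal[
    "pathogenic", "likely-pathogenic", "conflicting", "VUS", "benign", "absent"
]

Segregation = Literal["consistent", "inconsistent", "unavailable"]

#: population databases queried for allele frequencies, in reporting order
MAF_DATABASES = ("1000G", "EVS", "ExAC", "GnomAD", "dbSNP", "CSVS")


class SpliceScoreSet(BaseModel):
    """Wild-type/mutant score pairs from the external splice predictors.

    Scores are produced outside this package (MaxEntScan and HSF via the
    Human Splicing Finder portal, NNSPLICE); this type only carries them.
    ``site`` distinguishes loss of a native splice site from gain of a
    cryptic one — the two use different reference scores when the relative
    score change is computed (see :mod:`secondhit.splice`).
    """

    event: Literal["donor", "acceptor"]
    site: Literal["native-site-loss", "cryptic-site-gain"]
    maxent_wt: Optional[float] = None
    maxent_mut: Optional[float] = None
    hsf_wt: Optional[float] = None
    hsf_mut: Optional[float] = None
    nnsplice_wt: Optional[float] = None
    nnsplice_mut: Optional[float] = None

    @field_validator("hsf_wt", "hsf_mut")
    @classmethod
    def _hsf_range(cls, v):
        if v is not None and not (0.0 <= v <= 100.0):
            raise ValueError(f"HSF scores lie in [0, 100], got {v}")
        return v

    @field_validator("nnsplice_wt", "nnsplice_mut")
    @classmethod
    def _nns_range(cls, v):
        if v is not None and not (0.0 <= v <= 1.0):
            raise ValueError(f"NNSPLICE scores lie in [0, 1], got {v}")
        return v

    def tool_scores(self, tool: str) -> tuple[Optional[float], Optional[float]]:
        key = {"MaxEnt": "maxent", "HSF": "hsf", "NNSPLICE": "nnsplice"}[tool]
        return getattr(self, f"{key}_wt"), getattr(self, f"{key}_mut")

    def available_tools(self) -> list[str]:
        out = []
        for tool in ("MaxEnt", "HSF", "NNSPLICE"):
            wt, mut = self.tool_scores(tool)
            if wt is not None or mut is not None:
                out.append(tool)
        return out


class VariantRecord(BaseModel):
    """One annotated variant as consumed by the screening and prioritization
    stages.

    ``chrom``/``pos``/``ref``/``alt`` identify the variant genomically where
    known; cohort-fixture entries transcribed from published HGVS strings may
    carry only ``gene`` + ``hgvs_c``. ``maf`` maps database name to the
    frequency reported there; a database absent from the map means the
    variant was not observed in it.
    """

    variant_id: Optional[str] = None
    chrom: Optional[str] = None
    pos: Optional[int] = Field(default=None, ge=1)
    ref: Optional[str] = None
    alt: Optional[str] = None
    gene: str
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    consequence: Consequence = "other"
    zygosity: Zygosity = "het"
    dp: Optional[int] = Field(default=None, ge=0)
    fs: Optional[float] = Field(default=None, ge=0.0)
    maf: dict[str, float] = Field(default_factory=dict)
    splice: Optional[SpliceScoreSet] = None
    db_label: DbLabel = "absent"
    # majority of database submissions when db_label == "conflicting"
    conflicting_majority: Optional[Literal["pathogenic", "benign", "mixed"]] = None
    protein_predictions: dict[str, str] = Field(default_factory=dict)
    novel: bool = False
    segregation: Segregation = "unavailable"

    @field_validator("maf")
    @classmethod
    def _maf_range(cls, v):
        for db, f in v.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"MAF for {db} outside [0, 1]: {f}")
        return v

    @property
    def is_cnv(self) -> bool:
        return self.consequence in ("cnv-deletion", "cnv-duplication")

    def max_maf(self) -> Optional[float]:
        """Largest frequency across databases where the variant is observed."""
        return max(self.maf.values()) if self.maf else None


# ---------------------------------------------------------------------------
# VCF-lite TSV

_SPLICE_COLS = {
    "MAXENT_WT": "maxent_wt",
    "MAXENT_MUT": "maxent_mut",
    "HSF_WT": "hsf_wt",
    "HSF_MUT": "hsf_mut",
    "NNS_WT": "nnsplice_wt",
    "NNS_MUT": "nnsplice_mut",
}

_BASE_COLS = [
    "VARIANT_ID", "CHROM", "POS", "REF", "ALT", "GENE", "HGVS_C", "HGVS_P",
    "CONSEQUENCE", "ZYGOSITY", "DP", "FS",
]
_TAIL_COLS = list(_SPLICE_COLS) + ["EVENT", "SITE", "DB_LABEL", "NOVEL", "SEGREGATION"]


def _cell(v):
    if v is None:
        return ""
    return v


def to_table(records: list[VariantRecord]) -> pd.DataFrame:
    """Render records as a VCF-lite DataFrame (one ``MAF_<DB>`` column per
    database; empty cell = not observed)."""
    rows = []
    for r in records:
        row = {
            "VARIANT_ID": _cell(r.variant_id),
            "CHROM": _cell(r.chrom),
            "POS": _cell(r.pos),
            "REF": _cell(r.ref),
            "ALT": _cell(r.alt),
            "GENE": r.gene,
            "HGVS_C": _cell(r.hgvs_c),
            "HGVS_P": _cell(r.hgvs_p),
            "CONSEQUENCE": r.consequence,
            "ZYGOSITY": r.zygosity,
            "DP": _cell(r.dp),
            "FS": _cell(r.fs),
        }
        for db in MAF_DATABASES:
            row[f"MAF_{db}"] = r.maf.get(db, "")
        for col, attr in _SPLICE_COLS.items():
            row[col] = _cell(getattr(r.splice, attr)) if r.splice else ""
        row["EVENT"] = r.splice.event if r.splice else ""
        row["SITE"] = r.splice.site if r.splice else ""
        row["DB_LABEL"] = r.db_label
        row["NOVEL"] = int(r.novel)
        row["SEGREGATION"] = r.segregation
        rows.append(row)
    cols = _BASE_COLS + [f"MAF_{db}" for db in MAF_DATABASES] + _TAIL_COLS
    return pd.DataFrame(rows, columns=cols)


def _parse_opt(value, cast):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return cast(value)


def from_table(table: pd.DataFrame) -> list[VariantRecord]:
    """Parse a VCF-lite DataFrame back into records."""
    records = []
    for _, row in table.iterrows():
        maf = {}
        for db in MAF_DATABASES:
            col = f"MAF_{db}"
            if col in row:
                v = _parse_opt(row[col], float)
                if v is not None:
                    maf[db] = v
        splice = None
        scores = {
            attr: _parse_opt(row.get(col), float) for col, attr in _SPLICE_COLS.items()
        }
        if any(v is not None for v in scores.values()):
            splice = SpliceScoreSet(
                event=_parse_opt(row.get("EVENT"), str) or "donor",
                site=_parse_opt(row.get("SITE"), str) or "native-site-loss",
                **scores,
            )
        records.append(
            VariantRecord(
                variant_id=_parse_opt(row.get("VARIANT_ID"), str),
                chrom=_parse_opt(row.get("CHROM"), str),
                pos=_parse_opt(row.get("POS"), int),
                ref=_parse_opt(row.get("REF"), str),
                alt=_parse_opt(row.get("ALT"), str),
                gene=str(row["GENE"]),
                hgvs_c=_parse_opt(row.get("HGVS_C"), str),
                hgvs_p=_parse_opt(row.get("HGVS_P"), str),
                consequence=str(row.get("CONSEQUENCE", "other")),
                zygosity=str(row.get("ZYGOSITY", "het")),
                dp=_parse_opt(row.get("DP"), int),
                fs=_parse_opt(row.get("FS"), float),
                maf=maf,
                splice=splice,
                db_label=_parse_opt(row.get("DB_LABEL"), str) or "absent",
                novel=bool(_parse_opt(row.get("NOVEL"), int) or 0),
                segregation=_parse_opt(row.get("SEGREGATION"), str) or "unavailable",
            )
        )
    return records


def write_tsv(records: list[VariantRecord], path) -> None:
    to_table(records).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> list[VariantRecord]:
    return from_table(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))
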