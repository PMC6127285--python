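"""The packaged 29-family cohort and the gene-phenotype map.

The fixture transcribes a published cohort of 29 unrelated Spanish
families with inherited retinal dystrophies, 25 of which entered the study
carrying a single previously detected heterozygous variant in USH2A,
ABCA4 or CEP290. Each family carries its clinical diagnosis class, the
prior (monoallelic) variants, and the candidate variants reported for it,
with HGVS strings kept verbatim as printed. ``printed_status`` records the
published per-family outcome so the prioritization engine's own output can
be checked against it; the engine never reads it.

The schema is documented in ``docs/cohort_schema.md``. Entries that could
not be transcribed mechanically (inferred novelty flags, synthetic MAF and
splice-score stand-ins) are flagged there.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Literal, Optional

from pydantic import BaseModel, Field, ValidationError, field_validator

from .variants import VariantRecord

DiagnosisClass = Literal["arRP", "sRP", "LCA", "STGD", "USH", "COD"]

#: genes the cohort's prior monoallelic variants may occur in
PRIOR_GENES = ("ABCA4", "USH2A", "CEP290")


class FamilyCase(BaseModel):
    """One family: phenotype, prior variant(s) and screened candidates."""

    family_id: str
    index_id: str = "II:1"
    diagnosis: DiagnosisClass
    phenotype_notes: str = ""
    inheritance: Literal["autosomal-recessive", "simplex"]
    relatives_available: bool = False
    prior_variant_ids: list[str] = Field(default_factory=list)
    candidates: list[VariantRecord] = Field(default_factory=list)
    printed_status: Literal["solved", "candidate", "unsolved"]
    printed_status_gene: Optional[str] = None
    provenance: str = ""

    @field_validator("candidates")
    @classmethod
    def _unique_ids(cls, v):
        ids = [c.variant_id for c in v if c.variant_id]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate variant ids within a family")
        return v

    def prior_variants(self) -> list[VariantRecord]:
        """Prior variants still present among candidates.

        Tolerant of missing ids: a prior variant may legitimately drop out
        of a screened copy of the case (e.g. rejected by the MAF filter).
        """
        by_id = {c.variant_id: c for c in self.candidates}
        return [by_id[i] for i in self.prior_variant_ids if i in by_id]

    def prior_genes(self) -> list[str]:
        seen = []
        for v in self.prior_variants():
            if v.gene not in seen:
                seen.append(v.gene)
        return seen


class CohortFixture(BaseModel):
    families: list[FamilyCase]

    @field_validator("families")
    @classmethod
    def _unique_families(cls, v):
        ids = [f.family_id for f in v]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate family ids in cohort")
        return v

    def family(self, family_id: str) -> FamilyCase:
        for f in self.families:
            if f.family_id == family_id:
                return f
        raise KeyError(family_id)

    def n_with_prior_variant(self, gene: str | None = None) -> int:
        n = 0
        for f in self.families:
            genes = f.prior_genes()
            if genes and (gene is None or genes[0] == gene):
                n += 1
        return n


class CohortSchemaError(ValueError):
    """Raised when the packaged (or a user-edited) fixture fails validation."""


def _validate_family_dict(entry: dict, position: int) -> FamilyCase:
    fam_id = entry.get("family_id", f"#{position}")
    try:
        fam = FamilyCase.model_validate(entry)
        present = {c.variant_id for c in fam.candidates}
        dangling = [i for i in fam.prior_variant_ids if i not in present]
        if dangling:
            raise ValueError(f"prior variant ids {dangling} not among candidates")
    except (ValidationError, ValueError) as exc:
        raise CohortSchemaError(
            f"cohort fixture entry for family {fam_id!r} is malformed: {exc}"
        ) from exc
    if fam.prior_genes() and fam.prior_genes()[0] not in PRIOR_GENES:
        raise CohortSchemaError(
            f"family {fam.family_id!r}: prior variant gene "
            f"{fam.prior_genes()[0]!r} outside the cohort definition "
            f"{PRIOR_GENES}"
        )
    return fam


def load_cohort_dict(data: dict) -> CohortFixture:
    families = [
        _validate_family_dict(entry, i)
        for i, entry in enumerate(data.get("families", []))
    ]
    try:
        return CohortFixture(families=families)
    except ValidationError as exc:
        raise CohortSchemaError(f"cohort fixture malformed: {exc}") from exc


def load_cohort_fixture(path=None) -> CohortFixture:
    """Load the packaged 29-family cohort (or a compatible JSON file)."""
    if path is not None:
        with open(path) as fh:
            return load_cohort_dict(json.load(fh))
    text = resources.files("secondhit.data").joinpath("cohort.json").read_text()
    return load_cohort_dict(json.loads(text))


# ---------------------------------------------------------------------------
# gene-phenotype map


class GeneInfo(BaseModel):
    inheritance: Literal["recessive", "dominant"]
    phenotypes: list[str]


def load_gene_phenotypes(path=None) -> dict[str, GeneInfo]:
    """Gene -> (inheritance mode, associated diagnosis classes).

    A miniature RetNet-style association map covering the genes occurring
    in the packaged cohort plus a representative set of panel genes; the
    prioritization engine uses it for exact (non-fuzzy) phenotype
    consistency lookups.
    """
    if path is not None:
        with open(path) as fh:
            raw = json.load(fh)
    else:
        raw = json.loads(
            resources.files("secondhit.data")
            .joinpath("gene_phenotypes.json")
            .read_text()
        )
    return {gene: GeneInfo.model_validate(info) for gene, info in raw.items()}
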