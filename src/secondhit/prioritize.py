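"""Stepwise second-hit prioritization and causality classification.

For each family the engine searches, in order:

1. a second hit in the gene of the previously known monoallelic variant —
   SNVs/indels, splice-flagged intronic/synonymous variants, and CNV
   alleles; then
2. recessive two-allele (or dominant one-allele) explanations in any
   other panel gene.

Each allele is graded by :func:`assess_causality`. A variant is **causal**
when it is database-pathogenic (or novel with a damaging consequence or
prediction), consistent with the family phenotype, and segregation — when
performed — does not contradict it; a variant whose segregation places it
in cis with the prior variant is **excluded**; plausible alleles with
incomplete evidence (deep-intronic pairs without segregation, novel
variants with partial predictor support) grade **candidate**.

A family is *solved* when a genotype model is completed entirely by
causal alleles (one homozygous, or two heterozygotes assumed in trans —
flagged when phase is unconfirmed), *candidate* when a model completes
only at candidate grade, otherwise *unsolved*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .cnv import CnvCall
from .cohort import FamilyCase, GeneInfo, load_gene_phenotypes
from .splice import SpliceVerdict, evaluate_variant
from .variants import VariantRecord

Classification = Literal["causal", "candidate", "excluded"]

#: consequence classes that are damaging by nature of the lesion
_TRUNCATING = ("nonsense", "frameshift", "cnv-deletion", "cnv-duplication")
#: consequence classes whose damage evidence is the splice verdict
_SPLICE_CLASSES = ("intronic-splicing", "synonymous-splice", "deep-intronic")


@dataclass
class CausalityAssessment:
    """Per-variant criteria flags and the classification derived from them."""

    variant: VariantRecord
    segregates: Literal["yes", "no", "NA"]
    database_pathogenic: bool
    novel_with_damaging_prediction: bool
    phenotype_consistent: bool
    splice_flagged: Optional[bool]
    classification: Classification
    rationale: list[str] = field(default_factory=list)

    @property
    def variant_id(self) -> Optional[str]:
        return self.variant.variant_id


@dataclass
class PrioritizationResult:
    family_id: str
    status: Literal["solved", "candidate", "unsolved"]
    causal_gene: Optional[str]
    causal_alleles: list[CausalityAssessment]
    assessments: list[CausalityAssessment]
    notes: list[str] = field(default_factory=list)

    def allele_ids(self) -> list[str]:
        return [a.variant_id or "?" for a in self.causal_alleles]


def _protein_prediction_support(variant: VariantRecord) -> tuple[bool, bool]:
    """(majority damaging, any non-benign support) over available predictors."""
    votes = list(variant.protein_predictions.values())
    if not votes:
        return False, False
    damaging = sum(v == "damaging" for v in votes)
    benign = sum(v == "benign" for v in votes)
    partial = any(v in ("damaging", "possibly-damaging") for v in votes)
    return damaging > benign and damaging >= 1, partial


def assess_causality(
    variant: VariantRecord,
    case: FamilyCase,
    splice_verdict: Optional[SpliceVerdict] = None,
    gene_map: Optional[dict[str, GeneInfo]] = None,
) -> CausalityAssessment:
    """Grade one screened variant against the causality criteria."""
    gene_map = gene_map if gene_map is not None else load_gene_phenotypes()
    rationale: list[str] = []

    segregates = {"consistent": "yes", "inconsistent": "no",
                  "unavailable": "NA"}[variant.segregation]

    info = gene_map.get(variant.gene)
    phenotype_consistent = bool(info and case.diagnosis in info.phenotypes)
    if not info:
        rationale.append(f"gene {variant.gene} absent from phenotype map")

    db_path = variant.db_label in ("pathogenic", "likely-pathogenic") or (
        variant.db_label == "conflicting"
        and variant.conflicting_majority == "pathogenic"
    )
    db_benign = variant.db_label == "benign" or (
        variant.db_label == "conflicting"
        and variant.conflicting_majority == "benign"
    )

    flagged: Optional[bool] = None
    if splice_verdict is not None:
        flagged = splice_verdict.flagged
    elif variant.splice is not None:
        flagged = evaluate_variant(variant.splice).flagged

    pred_majority, pred_partial = _protein_prediction_support(variant)
    if variant.consequence in _TRUNCATING:
        damaging = True
        rationale.append(f"{variant.consequence}: damaging by lesion type")
    elif variant.consequence in _SPLICE_CLASSES:
        damaging = bool(flagged)
        rationale.append(
            "splice predictors " + ("support impact" if flagged else "negative")
        )
    else:
        damaging = pred_majority
    novel_damaging = variant.novel and damaging

    if segregates == "no":
        classification: Classification = "excluded"
        rationale.append("does not segregate with disease (in cis)")
    elif not phenotype_consistent:
        classification = "excluded"
        rationale.append(
            f"phenotype {case.diagnosis} not associated with {variant.gene}"
        )
    elif db_benign:
        classification = "excluded"
        rationale.append("database consensus benign")
    elif db_path or novel_damaging:
        if variant.consequence == "deep-intronic" and segregates == "NA":
            classification = "candidate"
            rationale.append(
                "deep-intronic without segregation: capped at candidate"
            )
        else:
            classification = "causal"
            rationale.append(
                "database pathogenic" if db_path else "novel with damaging evidence"
            )
    elif flagged or pred_partial or (
        variant.db_label == "conflicting"
        and variant.conflicting_majority == "mixed"
    ):
        classification = "candidate"
        rationale.append("partial predictor/database support only")
    else:
        classification = "excluded"
        rationale.append("insufficient evidence")

    return CausalityAssessment(
        variant=variant,
        segregates=segregates,
        database_pathogenic=db_path,
        novel_with_damaging_prediction=novel_damaging,
        phenotype_consistent=phenotype_consistent,
        splice_flagged=flagged,
        classification=classification,
        rationale=rationale,
    )


@dataclass
class GenotypeModel:
    gene: str
    grade: Literal["solved", "candidate"]
    alleles: list[CausalityAssessment]
    notes: list[str] = field(default_factory=list)


def check_genotype_model(
    alleles: list[CausalityAssessment],
    inheritance_mode: Literal["recessive", "dominant"],
) -> Literal["completed", "incomplete"]:
    """Can these graded alleles of one gene complete a genotype?

    Recessive: one homozygous causal allele or >= 2 heterozygous causal
    alleles (assumed in trans when unphased). Dominant: one heterozygous
    causal allele whose segregation is confirmed.
    """
    model = _best_gene_model(
        alleles[0].variant.gene if alleles else "?", alleles, inheritance_mode
    )
    return "completed" if model is not None and model.grade == "solved" else "incomplete"


def _best_gene_model(
    gene: str,
    assessments: list[CausalityAssessment],
    mode: Literal["recessive", "dominant"],
) -> Optional[GenotypeModel]:
    causal = [a for a in assessments if a.classification == "causal"]
    candidate = [a for a in assessments if a.classification == "candidate"]
    usable = causal + candidate

    def phase_notes(chosen: list[CausalityAssessment]) -> list[str]:
        hets = [a for a in chosen if a.variant.zygosity == "het"]
        if len(hets) >= 2 and any(a.segregates != "yes" for a in hets):
            return ["phase unconfirmed: heterozygous alleles assumed in trans"]
        return []

    if mode == "dominant":
        seg_confirmed = [a for a in causal if a.segregates == "yes"]
        if seg_confirmed:
            return GenotypeModel(gene, "solved", seg_confirmed[:1])
        if usable:
            return GenotypeModel(
                gene, "candidate", usable[:1],
                notes=["dominant allele without confirmed segregation"],
            )
        return None

    hom_causal = [a for a in causal if a.variant.zygosity == "hom"]
    het_causal = [a for a in causal if a.variant.zygosity == "het"]
    if len(hom_causal) >= 2:
        return GenotypeModel(
            gene, "candidate", hom_causal,
            notes=["contradictory zygosity: two homozygous causal alleles"],
        )
    if len(hom_causal) == 1:
        return GenotypeModel(gene, "solved", hom_causal)
    if len(het_causal) >= 2:
        chosen = sorted(het_causal, key=lambda a: a.variant_id or "")
        return GenotypeModel(gene, "solved", chosen, notes=phase_notes(chosen))

    hom_usable = [a for a in usable if a.variant.zygosity == "hom"]
    het_usable = [a for a in usable if a.variant.zygosity == "het"]
    if hom_usable:
        return GenotypeModel(gene, "candidate", hom_usable[:1])
    if len(het_usable) >= 2:
        chosen = sorted(het_usable, key=lambda a: a.variant_id or "")
        return GenotypeModel(gene, "candidate", chosen, notes=phase_notes(chosen))
    return None


def cnv_call_to_variant(call: CnvCall) -> VariantRecord:
    """Reduce a CNV call to an allele of its gene for prioritization."""
    consequence = (
        "cnv-deletion" if call.direction == "deletion" else "cnv-duplication"
    )
    start, end = call.refined_breakpoints or (call.start, call.end)
    return VariantRecord(
        variant_id=f"cnv:{call.sample}:{call.chrom}:{start}-{end}",
        chrom=call.chrom,
        pos=start,
        gene=call.gene or "NA",
        hgvs_c=f"g.{start}_{end}{'del' if call.direction == 'deletion' else 'dup'}",
        consequence=consequence,
        zygosity="hom" if call.zygosity == "homozygous" else "het",
        novel=True,
    )


def prioritize_family(
    case: FamilyCase,
    splice_verdicts: Optional[dict[str, SpliceVerdict]] = None,
    cnv_calls: Optional[list[CnvCall]] = None,
    gene_map: Optional[dict[str, GeneInfo]] = None,
) -> PrioritizationResult:
    """Run the stepwise search for one family.

    ``case.candidates`` are expected to have passed the QC/MAF screen.
    ``splice_verdicts`` maps variant id to a precomputed verdict (computed
    from the record's own scores when absent); ``cnv_calls`` contributes
    additional CNV alleles for the index sample.
    """
    gene_map = gene_map if gene_map is not None else load_gene_phenotypes()
    splice_verdicts = splice_verdicts or {}

    variants = list(case.candidates)
    for call in cnv_calls or []:
        variants.append(cnv_call_to_variant(call))

    assessments = [
        assess_causality(
            v, case,
            splice_verdict=splice_verdicts.get(v.variant_id or ""),
            gene_map=gene_map,
        )
        for v in variants
    ]

    by_gene: dict[str, list[CausalityAssessment]] = {}
    for a in assessments:
        by_gene.setdefault(a.variant.gene, []).append(a)

    # prior genes first, then the remaining genes deterministically
    prior = [g for g in case.prior_genes() if g in by_gene]
    others = sorted(g for g in by_gene if g not in prior)
    order = prior + others

    models: list[GenotypeModel] = []
    for gene in order:
        info = gene_map.get(gene)
        mode = info.inheritance if info else "recessive"
        model = _best_gene_model(gene, by_gene[gene], mode)
        if model is not None:
            models.append(model)

    chosen: Optional[GenotypeModel] = None
    for model in models:  # order already encodes the search priority
        if model.grade == "solved":
            chosen = model
            break
    if chosen is None:
        for model in models:
            if model.grade == "candidate":
                chosen = model
                break

    if chosen is None:
        return PrioritizationResult(
            family_id=case.family_id, status="unsolved", causal_gene=None,
            causal_alleles=[], assessments=assessments,
            notes=["no completable genotype model"],
        )

    notes = list(chosen.notes)
    if case.prior_variant_ids and chosen.gene in case.prior_genes():
        notes.append("second hit in the gene of the prior variant")
    elif case.prior_variant_ids:
        notes.append("different locus than prior variant")
    status = "solved" if chosen.grade == "solved" else "candidate"
    return PrioritizationResult(
        family_id=case.family_id, status=status, causal_gene=chosen.gene,
        causal_alleles=chosen.alleles, assessments=assessments, notes=notes,
    )
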