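"""Cohort-level diagnostic reporting.

Aggregates per-family prioritization results into the summary statistics a
diagnostic study reports: diagnostic yield, per-diagnosis solved counts
with the implicated genes, the mutation-type spectrum, novel and recurrent
alleles, and second-hit rates by prior gene.

Allele-counting convention: per family, a homozygous genotype contributes
**one** counted mutation, and a recurrent allele is counted once per
family carrying it. Percentages use the counted-occurrence denominator
and round half-up to the printed precision (1 decimal for the spectrum,
2 for the yield).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .cohort import CohortFixture
from .prioritize import PrioritizationResult

#: spectrum categories; splicing pools intronic-splicing + synonymous-splice
_SPECTRUM = {
    "missense": ("missense",),
    "splicing": ("intronic-splicing", "synonymous-splice"),
    "frameshift": ("frameshift",),
    "nonsense": ("nonsense",),
    "CNV": ("cnv-deletion", "cnv-duplication"),
    "deep-intronic": ("deep-intronic",),
    "other": ("other",),
}


def round_half_up(x: float, digits: int) -> float:
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n_families: int
    n_solved: int
    n_candidate: int
    n_unsolved: int
    yield_percent: float
    statuses: dict[str, str]
    by_diagnosis: dict[str, dict]  # diagnosis -> {solved, total, genes{}}
    solved_by_gene: dict[str, int]
    n_causal_mutations: int
    spectrum_counts: dict[str, int]
    spectrum_percent: dict[str, float]  # half-up, 1 dp
    spectrum_percent_raw: dict[str, float]
    n_novel: int
    recurrent_alleles: dict[str, list[str]]  # allele -> carrying families
    second_hit_rate: dict[str, dict]  # prior gene -> {solved_same_gene, carriers}
    notes: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        """Human-readable per-diagnosis table plus headline numbers."""
        lines = [
            f"Families: {self.n_families}  solved: {self.n_solved}  "
            f"candidate: {self.n_candidate}  unsolved: {self.n_unsolved}",
            f"Diagnostic yield: {self.yield_percent}%",
            "",
            f"{'Clinical diagnosis':<22}{'Solved/Total':<14}Genes (families)",
        ]
        for diag, row in self.by_diagnosis.items():
            genes = ", ".join(f"{g} ({n})" for g, n in row["genes"].items()) or "-"
            lines.append(f"{diag:<22}{row['solved']}/{row['total']:<13}{genes}")
        lines.append("")
        lines.append(
            f"Causal mutations: {self.n_causal_mutations} "
            f"({self.n_novel} novel)"
        )
        for cat, n in self.spectrum_counts.items():
            if n:
                lines.append(f"  {cat:<14}{n:>3}  {self.spectrum_percent[cat]}%")
        for note in self.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)


def summarize(
    results: list[PrioritizationResult], cohort: CohortFixture
) -> CohortSummary:
    """Aggregate per-family results; deterministic and order-invariant."""
    seen = set()
    for r in results:
        if r.family_id in seen:
            raise ValueError(f"duplicate family_id in results: {r.family_id}")
        seen.add(r.family_id)

    by_family = {f.family_id: f for f in cohort.families}
    results = sorted(results, key=lambda r: list(by_family).index(r.family_id)
                     if r.family_id in by_family else len(by_family))

    statuses = {r.family_id: r.status for r in results}
    n_solved = sum(s == "solved" for s in statuses.values())
    n_candidate = sum(s == "candidate" for s in statuses.values())
    n = len(results)
    yield_percent = round_half_up(100.0 * n_solved / n, 2) if n else 0.0

    # per-diagnosis table (solved families only contribute gene counts)
    by_diagnosis: dict[str, dict] = {}
    solved_by_gene: dict[str, int] = {}
    for r in results:
        fam = by_family.get(r.family_id)
        if fam is None:
            continue
        row = by_diagnosis.setdefault(
            fam.diagnosis, {"solved": 0, "total": 0, "genes": {}}
        )
        row["total"] += 1
        if r.status == "solved":
            row["solved"] += 1
            row["genes"][r.causal_gene] = row["genes"].get(r.causal_gene, 0) + 1
            solved_by_gene[r.causal_gene] = solved_by_gene.get(r.causal_gene, 0) + 1

    # allele counting: hom = one occurrence; recurrent = once per family
    spectrum_counts = {cat: 0 for cat in _SPECTRUM}
    n_novel = 0
    carriers: dict[str, list[str]] = {}
    total_occurrences = 0
    for r in results:
        if r.status != "solved":
            continue
        for a in r.causal_alleles:
            total_occurrences += 1
            cons = a.variant.consequence
            for cat, members in _SPECTRUM.items():
                if cons in members:
                    spectrum_counts[cat] += 1
                    break
            if a.variant.novel:
                n_novel += 1
            if a.variant_id:
                carriers.setdefault(a.variant_id, []).append(r.family_id)

    spectrum_percent_raw = {
        cat: (100.0 * c / total_occurrences if total_occurrences else 0.0)
        for cat, c in spectrum_counts.items()
    }
    spectrum_percent = {
        cat: round_half_up(v, 1) for cat, v in spectrum_percent_raw.items()
    }

    recurrent = {
        vid: fams for vid, fams in sorted(carriers.items()) if len(fams) >= 2
    }

    second_hit: dict[str, dict] = {}
    for fam in cohort.families:
        genes = fam.prior_genes()
        if not genes:
            continue
        gene = genes[0]
        row = second_hit.setdefault(gene, {"solved_same_gene": 0, "carriers": 0})
        row["carriers"] += 1
        r = next((x for x in results if x.family_id == fam.family_id), None)
        if r is not None and r.status == "solved" and r.causal_gene == gene:
            row["solved_same_gene"] += 1

    notes = []
    if n_solved:
        top_gene = max(solved_by_gene, key=solved_by_gene.get)
        share = round_half_up(100.0 * solved_by_gene[top_gene] / n_solved, 2)
        notes.append(
            f"{solved_by_gene[top_gene]} of {n_solved} solved families "
            f"({share}%) are explained by {top_gene}"
        )
    return CohortSummary(
        n_families=n,
        n_solved=n_solved,
        n_candidate=n_candidate,
        n_unsolved=n - n_solved - n_candidate,
        yield_percent=yield_percent,
        statuses=statuses,
        by_diagnosis=by_diagnosis,
        solved_by_gene=solved_by_gene,
        n_causal_mutations=total_occurrences,
        spectrum_counts=spectrum_counts,
        spectrum_percent=spectrum_percent,
        spectrum_percent_raw=spectrum_percent_raw,
        n_novel=n_novel,
        recurrent_alleles=recurrent,
        second_hit_rate=second_hit,
        notes=notes,
    )
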