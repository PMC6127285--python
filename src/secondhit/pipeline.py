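"""End-to-end cohort pipeline: screen -> splice-eval -> prioritize.

Thin orchestration over the stage modules, so the whole analysis of a
cohort fixture (or any compatible cohort file) is one call.
"""

from __future__ import annotations

from typing import Optional

from .cohort import CohortFixture, FamilyCase, GeneInfo, load_gene_phenotypes
from .prioritize import PrioritizationResult, prioritize_family
from .screen import ScreenConfig, screen
from .splice import Policy, SpliceVerdict, evaluate_variant


def screen_family(case: FamilyCase, config: ScreenConfig | None = None) -> FamilyCase:
    """Return a copy of the case with only screen-passing candidates."""
    retained, _ = screen(case.candidates, config)
    return case.model_copy(update={"candidates": retained})


def splice_verdicts_for(
    case: FamilyCase, policy: Policy = "majority"
) -> dict[str, SpliceVerdict]:
    out: dict[str, SpliceVerdict] = {}
    for v in case.candidates:
        if v.splice is not None and v.variant_id:
            out[v.variant_id] = evaluate_variant(v.splice, policy=policy)
    return out


def run_cohort(
    fixture: CohortFixture,
    screen_config: ScreenConfig | None = None,
    policy: Policy = "majority",
    gene_map: Optional[dict[str, GeneInfo]] = None,
) -> list[PrioritizationResult]:
    """Screen, splice-evaluate and prioritize every family of a cohort."""
    gene_map = gene_map if gene_map is not None else load_gene_phenotypes()
    results = []
    for case in fixture.families:
        screened = screen_family(case, screen_config)
        verdicts = splice_verdicts_for(screened, policy)
        results.append(
            prioritize_family(screened, splice_verdicts=verdicts, gene_map=gene_map)
        )
    return results
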