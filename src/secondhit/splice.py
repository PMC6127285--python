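"""Decision thresholds over externally produced splice-predictor scores.

Intronic and synonymous variants are flagged as predicted splice-altering
from wild-type/mutant score pairs of three predictors. A tool passes when
the biologically active site scores above the tool's minimum *and* the
relative score change exceeds the tool's variation threshold:

=========  ==============  =====================
tool       minimum score   score variation
=========  ==============  =====================
MaxEnt     >= 2            > 15 %
HSF        >= 70           > 10 %
NNSPLICE   > 0.4           > 10 %
=========  ==============  =====================

For loss of a native site the minimum applies to the wild-type score and
the variation is computed relative to it; for gain of a cryptic site the
new (mutant) site is the active one, so both apply to the mutant score —
which also keeps the relative change well defined when the wild-type
score is 0. A variant is flagged when a configurable combination of the
available tools passes (default: strict majority).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .variants import SpliceScoreSet

Policy = Literal["majority", "any", "all"]

#: (minimum active-site score, score-inclusive?, variation threshold %)
_TOOL_RULES = {
    "MaxEnt": (2.0, True, 15.0),
    "HSF": (70.0, True, 10.0),
    "NNSPLICE": (0.4, False, 10.0),
}

TOOLS = tuple(_TOOL_RULES)


@dataclass
class SpliceVerdict:
    per_tool: dict[str, bool]
    flagged: bool
    policy: Policy
    rationale: list[str] = field(default_factory=list)


def evaluate_tool(
    tool: str,
    wild_type: Optional[float],
    mutant: Optional[float],
    site: Literal["native-site-loss", "cryptic-site-gain"] = "native-site-loss",
) -> Optional[bool]:
    """Pass flag for one predictor, or None if the tool gave no scores.

    A missing wild-type score for a cryptic gain (no site existed before
    the variant) is treated as 0.
    """
    if tool not in _TOOL_RULES:
        raise ValueError(f"unknown splice tool {tool!r}; expected one of {TOOLS}")
    if wild_type is None and mutant is None:
        return None
    min_score, inclusive, min_variation = _TOOL_RULES[tool]

    if site == "cryptic-site-gain":
        wild_type = wild_type if wild_type is not None else 0.0
        if mutant is None:
            return False
        active, denom = mutant, mutant
    else:
        if wild_type is None or mutant is None:
            return False
        active, denom = wild_type, wild_type

    score_ok = active >= min_score if inclusive else active > min_score
    if denom == 0:
        return False  # a zero active-site score can never pass the minimum
    variation = abs(mutant - wild_type) * 100.0 / denom
    return bool(score_ok and variation > min_variation)


def evaluate_variant(
    scores: SpliceScoreSet, policy: Policy = "majority"
) -> SpliceVerdict:
    """Combine per-tool outcomes into an overall splice-impact flag.

    ``majority`` requires a strict majority of the tools that produced
    scores (2 of 3, 2 of 2, 1 of 1); ``any``/``all`` are the obvious
    alternatives. At least one tool must be present.
    """
    per_tool: dict[str, bool] = {}
    rationale = []
    for tool in TOOLS:
        wt, mut = scores.tool_scores(tool)
        outcome = evaluate_tool(tool, wt, mut, site=scores.site)
        if outcome is None:
            continue
        per_tool[tool] = outcome
        rationale.append(
            f"{tool}: wt={wt} mut={mut} ({scores.site}) -> "
            f"{'pass' if outcome else 'fail'}"
        )
    if not per_tool:
        raise ValueError("no splice tool produced scores for this variant")

    n_pass = sum(per_tool.values())
    n_avail = len(per_tool)
    if policy == "any":
        flagged = n_pass >= 1
    elif policy == "all":
        flagged = n_pass == n_avail
    elif policy == "majority":
        flagged = n_pass > n_avail / 2
    else:
        raise ValueError(f"unknown policy {policy!r}")
    rationale.append(f"policy={policy}: {n_pass}/{n_avail} tools pass")
    return SpliceVerdict(per_tool=per_tool, flagged=flagged, policy=policy,
                         rationale=rationale)
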