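"""Apply the splice-predictor decision thresholds to score pairs.

A tool passes when the active site scores above the tool minimum and the
relative score change exceeds the tool's variation threshold; by default
a variant is flagged when a majority of available tools pass.
"""

import secondhit as sh
from secondhit.variants import SpliceScoreSet

# native donor site weakened by the variant: both tools see a large drop
loss = SpliceScoreSet(
    event="donor", site="native-site-loss",
    maxent_wt=8.2, maxent_mut=3.1, hsf_wt=88.0, hsf_mut=61.0,
)
# deep-intronic variant creating a cryptic donor where none existed
gain = SpliceScoreSet(
    event="donor", site="cryptic-site-gain",
    nnsplice_wt=0.0, nnsplice_mut=0.81, hsf_wt=41.0, hsf_mut=86.0,
)
# negligible score changes: predicted to have no impact
neutral = SpliceScoreSet(
    event="donor", site="native-site-loss",
    nnsplice_wt=0.85, nnsplice_mut=0.84, hsf_wt=80.0, hsf_mut=79.2,
)

for name, scores in [("site loss", loss), ("cryptic gain", gain),
                     ("no impact", neutral)]:
    verdict = sh.evaluate_variant(scores)
    print(f"{name}: flagged={verdict.flagged}")
    for line in verdict.rationale:
        print(f"  {line}")
# Flagged variants count as splice-damaging during prioritization; a
# variant whose predictions fail (like the third case) cannot be promoted
# on splice evidence alone.
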