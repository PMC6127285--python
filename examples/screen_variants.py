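"""QC and rare-frequency screening of a simulated variant table.

Draws a panel-scale variant table (2,349 variants of which ~314 are rare,
mirroring the per-patient load of a targeted IRD panel) and applies the
two record-level filters.
"""

import secondhit as sh

records = sh.simulate_variant_table(2349, rare_fraction=314 / 2349, seed=1)
retained, rejected = sh.screen(records)

reasons = {}
for r in rejected:
    key = r.reason.split("-in-")[0]
    reasons[key] = reasons.get(key, 0) + 1

print(f"input variants:  {len(records)}")
print(f"retained (rare, QC-passing): {len(retained)}")
for reason, n in sorted(reasons.items()):
    print(f"  rejected {reason}: {n}")
# Most variants are common polymorphisms removed by the MAF < 0.015
# screen; the few hundred retained are the rare candidates that enter
# prioritization.
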