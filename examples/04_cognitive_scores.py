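"""Neuropsychological scoring: raw subtests -> T1-anchored z -> delta scores.

Scores are z-scored against the first-timepoint group (frozen mean/SD),
aggregated into six domains, and differenced (T2 - T1; positive = better).
"""
import numpy as np
import pandas as pd

import megrsn as m

rng = np.random.default_rng(0)
subtests = list(m.default_battery().subtests)
rows = []
for tp in ("T1", "T2"):
    for subject in range(1, 9):
        rows.append({
            "subject": subject, "timepoint": tp,
            **{s: rng.normal(50, 10) for s in subtests},
        })
raw = pd.DataFrame(rows)

domains = m.domain_scores(raw)                # polarity-corrected, standardized
ztable = m.zscore_t1_anchored(domains)        # frozen T1 mean/SD per domain
deltas = m.delta_scores(ztable)

print("T1 group mean/SD per domain (anchoring):")
print(ztable.baseline_stats.round(3).to_string(index=False))
print("\ndelta scores (z units, positive = improvement):")
print(deltas.scores.round(2).to_string(index=False))

print("\nbundled reference delta table (ten-subject surgical cohort):")
print(m.load_reference_deltas().to_string(index=False))
# subjects 5 and 7 lack the follow-up assessment and stay missing
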