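"""Simulate a two-timepoint cohort with a known connectivity increase.

Ten subjects, two recordings each; at the second timepoint the 'NetA'
network's within-pair PLI is raised by 0.05 and the verbal-memory delta
score tracks each subject's realized connectivity change.
"""
import megrsn as m

labels = tuple(f"R{i}_{h}" for i in range(1, 7) for h in ("L", "R"))
registry = m.RoiRegistry(labels)
networks = [
    m.RsnDefinition("NetA", labels[:4]),
    m.RsnDefinition("NetB", labels[4:8]),
]
recording = m.CohortRecordingConfig(n_epochs=2, epoch_length=2048)

spec = m.CohortSpec(
    n_subjects=10,
    effect_networks=("NetA",),
    effect_size=0.05,  # target per-pair PLI increase at T2
    cognition_link={"verbal_memory": 15.0},
    seed=7,
    recording=recording,
)
cohort = m.generate_cohort(spec, registry, networks, store_recordings=False)

piv = cohort.summaries[cohort.summaries.network != "global"].pivot_table(
    index="network", columns="timepoint", values="mean_pli"
)
piv["delta"] = piv["T2"] - piv["T1"]
print("group-mean network PLI:")
print(piv.round(4))
# NetA's delta sits near the injected +0.05; NetB stays at baseline noise

print("\ncognitive delta scores (z units; verbal memory tracks NetA change):")
print(cohort.cognitive_deltas.round(2).to_string(index=False))
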