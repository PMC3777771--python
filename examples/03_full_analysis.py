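"""End-to-end analysis: cohort -> Wilcoxon per network -> FDR -> post hoc tau.

Stage 1 tests the global mean PLI per band, stage 2 each network within its
band family (Benjamini-Hochberg FDR per band), and stage 3 rank-correlates
the FDR-surviving cells' connectivity changes with all six cognitive
domains.  Negative z means the value increased after the intervention.
"""
import megrsn as m

labels = tuple(f"N{k}_{j}_{h}" for k in range(4) for j in (1, 2) for h in ("L", "R"))
registry = m.RoiRegistry(labels)
names = ["DMN", "FPN_left", "FPN_right", "ECN"]
networks = [
    m.RsnDefinition(name, labels[4 * k : 4 * k + 4]) for k, name in enumerate(names)
]

spec = m.CohortSpec(
    effect_networks=("DMN",),
    effect_size=0.05,
    cognition_link={"verbal_memory": 15.0},
    seed=3,
    recording=m.CohortRecordingConfig(n_epochs=2, epoch_length=2048),
)
cohort = m.generate_cohort(spec, registry, networks, store_recordings=False)
report = m.run_full_inference(cohort.summaries, cohort.cognitive_deltas)

print("stage 1+2 (paired Wilcoxon, FDR per band):")
print(report.paired_frame().round(4).to_string(index=False))
print("\nstage 3 (Kendall tau for FDR-surviving cells only):")
frame = report.correlation_frame()
print(frame.round(4).to_string(index=False) if len(frame) else "  (no surviving cells)")
# with this seed the DMN shows the injected increase (negative z) and the
# verbal-memory tau is the strongest positive correlation
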