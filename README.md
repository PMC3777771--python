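# megrsn

Phase-lag-index (PLI) connectivity analysis of resting-state networks (RSNs)
for source-space MEG, with a coupled-oscillator cohort simulator and the
longitudinal nonparametric statistics used in small surgical-cohort studies.

## The problem

Whether cognitive change after an intervention (for example resective brain
surgery in low-grade-glioma patients) is reflected in the functional
connectivity of specific resting-state networks is a question asked of
longitudinal MEG recordings: ten-or-so subjects, two measurement occasions
(pre-intervention T1, post-intervention T2), source-reconstructed activity in
the 78 cortical regions of the AAL parcellation, and a neuropsychological
battery covering six cognitive domains. This package implements the complete
analysis path from per-region source time series to the final statistical
report, and — because patient MEG recordings are rarely shareable — a
synthetic cohort generator with known ground truth so every stage can be
validated end to end.

## The statistic

For two signals with instantaneous phases φ_a(t_k), φ_b(t_k) (analytic
signal via the Hilbert transform), the phase lag index is

    PLI = | ⟨ sign( sin(φ_a(t_k) − φ_b(t_k)) ) ⟩ |,   Δφ ∈ [−π, π],

the absolute mean over time samples of the sign of the sine of the phase
difference. It measures the *asymmetry* of the phase-difference distribution
around zero: PLI = 1 means a consistent nonzero lag (total locking), PLI = 0
means no asymmetry. Because volume conduction mixes sources with zero lag, it
cannot create asymmetry — the PLI's defining robustness (for symmetric
two-channel mixing the invariance is exact: mixing rescales sin Δφ by a
positive constant at every sample).

The analysis pipeline: decimate (1250 Hz → 312.5 Hz), band-filter into six
bands (delta 0.5–4, theta 4–8, lower alpha 8–10, upper alpha 10–13, beta
13–30, lower gamma 30–48 Hz), cut five 4096-sample epochs (13.1072 s each),
average per-epoch PLI matrices over all 3003 region pairs, then mean the
within-network pairs of each RSN (default mode network, left/right
frontoparietal networks, executive control network). Inference is Wilcoxon
signed-ranks per band and network with Benjamini–Hochberg FDR applied within
each band's family, followed by post-hoc Kendall tau-b correlations between
the FDR-surviving networks' connectivity changes and the six cognitive-domain
delta scores (T1-anchored z-scores, T2 − T1).

## Worked example

```python
import numpy as np
import megrsn as m

rate = 312.5
t = np.arange(4096) / rate
pli = m.pli_pair(
    m.instantaneous_phase(np.cos(2 * np.pi * 9 * t), rate),
    m.instantaneous_phase(np.sin(2 * np.pi * 9 * t), rate),
)
print(pli)            # 1.0 — constant pi/2 lag, total phase locking
```

A full simulated study (`examples/03_full_analysis.py`) generates a
ten-subject cohort with a +0.05 PLI increase injected into the DMN at T2 and
a verbal-memory delta tied to each subject's realized connectivity change,
then runs the three-stage inference. Its output:

```
stage 1+2 (paired Wilcoxon, FDR per band):
       band   network  n       z      p method  p_fdr  fdr_significant
lower_alpha    global 10 -0.8664 0.4316  exact 0.4316            False
lower_alpha       DMN 10 -2.4973 0.0098  exact 0.0391             True
lower_alpha  FPN_left 10 -0.3568 0.7695  exact 0.7695            False
lower_alpha FPN_right 10 -0.7645 0.4922  exact 0.6562            False
lower_alpha       ECN 10 -1.5799 0.1309  exact 0.2617            False

stage 3 (Kendall tau for FDR-surviving cells only):
       band network                 domain  n     tau      p
lower_alpha     DMN  executive_functioning 10 -0.2889 0.2912
lower_alpha     DMN          verbal_memory 10  0.7778 0.0009
lower_alpha     DMN         working_memory 10 -0.5111 0.0466
lower_alpha     DMN information_processing 10 -0.2444 0.3807
lower_alpha     DMN              attention 10  0.2444 0.3807
lower_alpha     DMN      psychomotor_speed 10  0.4667 0.0726
```

Only the DMN shows a significant T2 increase (negative z by the convention
that increases give negative z), it survives FDR within its band, and the
linked domain (verbal memory) carries by far the strongest positive tau —
exactly the planted ground truth. (The nominally significant working-memory
tau is the kind of uncorrected post-hoc noise a ten-subject study produces.) The other examples cover the PLI primitives
(`01`), cohort simulation (`02`) and cognitive scoring (`04`); a thin
`megrsn` CLI (`simulate`, `connectivity`, `summarize`, `cognition`, `infer`,
`report`) wraps the same functions for shell use.

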