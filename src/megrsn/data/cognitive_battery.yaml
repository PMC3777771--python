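# Neuropsychological battery: subtest -> cognitive domain(s) mapping and
# score polarity.  higher_is_better: false marks timed tests (lower raw
# score = better performance); such scores are sign-flipped before
# standardization so that larger always means better.
domains:
  - executive_functioning
  - verbal_memory
  - working_memory
  - information_processing
  - attention
  - psychomotor_speed

subtests:
  concept_shifting:
    domains: [executive_functioning, psychomotor_speed]
    higher_is_better: false
  word_fluency:
    domains: [executive_functioning]
    higher_is_better: true
  rey_auditory_verbal_learning:
    domains: [verbal_memory]
    higher_is_better: true
  stroop_color_word:
    domains: [attention]
    higher_is_better: false
  memory_comparison:
    domains: [working_memory]
    higher_is_better: false
  letter_digit_substitution:
    domains: [information_processing, psychomotor_speed]
    higher_is_better: true
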