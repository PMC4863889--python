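# Default 7-domain / 22-outcome nesting of the neuropsychological battery.
# orientation -1 marks "lower raw score is better" columns (completion times
# and the Stroop interference ratio); these are sign-flipped before scaling.
domains:
  - domain_id: d1
    label: Primary Memory
    outcomes: [digit_span_total]
  - domain_id: d2
    label: Perceptual Speed
    outcomes: [digit_symbol_coding, stroop_words, stroop_dots]
  - domain_id: d3
    label: Verbal Episodic Memory
    outcomes:
      - logical_memory_1
      - logical_memory_2
      - cvlt_total_learning
      - cvlt_short_delay
      - cvlt_long_delay
      - cvlt_recognition
      - cvlt_dprime
  - domain_id: d4
    label: Visuospatial Function
    outcomes: [rcft_copy, rcft_copy_time]
  - domain_id: d5
    label: Visual Episodic Memory
    outcomes: [rcft_recall_3min, rcft_recall_30min, rcft_recognition]
  - domain_id: d6
    label: Verbal Ability
    outcomes: [bnt, letter_fluency, category_fluency, switching_fluency]
  - domain_id: d7
    label: Interference
    outcomes: [stroop_colours, stroop_interference]
orientation:
  stroop_words: -1
  stroop_dots: -1
  stroop_colours: -1
  stroop_interference: -1
  rcft_copy_time: -1
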