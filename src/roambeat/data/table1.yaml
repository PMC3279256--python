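# Nursing-home criteria: four caregiving activities, six artifacts.
# time_span is [t_min, t_max] in minutes; quantum in minutes (defaults to
# t_min); min_beats/max_beats bound the "beats established" per artifact.
# max_beats is advisory: the flag is raised at min_beats and extra beats
# before the quantum expires simply re-arm the quantum.
activities:
  feeding:
    time_span: [5, 50]
    quantum: 5
    mode: strict
    artifacts:
      tray: {min_beats: 2, max_beats: 2}
  blood_pressure:
    time_span: [5, 10]
    quantum: 5
    mode: strict
    artifacts:
      blood_pressure_device: {min_beats: 3, max_beats: 4}
  hygiene:
    time_span: [10, 30]
    quantum: 10
    mode: flexible
    k_required: 2
    artifacts:
      physiological_solution: {min_beats: 3}
      cream: {min_beats: 3}
      paper_towel: {min_beats: 6}
  medications:
    time_span: [3, 5]
    quantum: 3
    mode: strict
    artifacts:
      pillbox: {min_beats: 2}
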