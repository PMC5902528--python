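# Branched pipeline: one trunk, two competing artifact-correction branches,
# and a multi-source "peek" pipe that snapshots every node for comparison.
#   eegpipe simulate --out examples/data --subjects 2 --duration 60 --seed 1
#   eegpipe run --config examples/branched.yaml

project_root: output_branched
seed: 42

measurements: {dir: data, pattern: "*.bdf"}

global_args:
  veog_labels: [VEOG]
  event_code_map: {1: std_short, 2: std_long, 3: dev_short, 4: dev_long}

pipes:
  - id: "1"                  # trunk: reads raw data (no sources)
    step_sets:
      - id: 1_load
        steps:
          - op: rereference
          - op: detect_blink_events
          - op: highpass_filter
          - op: ica_decompose

  - id: 2A                   # branch A: tweaked variance detection, worst-5% cap
    sources: ["1#1_load"]    # start from the trunk's saved state
    step_sets:
      - id: 2_art
        steps:
          - op: detect_blink_ics
          - op: filter_blink_ics
          - op: detect_bad_channels_variance
            args: {bounds: [-5, 2.5], fraction_cap: 0.05}
          - op: reject_channels

  - id: 2B                   # branch B: multi-metric IC detection + spectral channels
    sources: ["1#1_load"]
    step_sets:
      - id: 2_art
        steps:
          - op: detect_bad_ics
            args: {match_logic: any}
          - op: reject_components
          - op: detect_bad_channels_spectral
          - op: reject_channels

  - id: peek                 # runs once per source; output dirs are labelled
    sources: ["1#1_load", "2A#2_art", "2B#2_art"]
    step_sets:
      - id: p
        save: false          # statistics only; the data is not meaningfully changed
        steps:
          - op: peek_data
            args: {n_segments: 4, seg_len_s: 5.0}
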