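# Basic linear pipeline: load -> prepare -> artifact correction -> peeks.
# Generate input data first:
#   eegpipe simulate --out examples/data --subjects 2 --duration 60 --seed 1
# then run:
#   eegpipe run --config examples/basic.yaml

project_root: output_basic
seed: 42
overwrite: false

measurements:
  dir: data        # scan a directory of BDF files ...
  pattern: "*.bdf"          # ... matching this glob; subject id = first "_" token
  # sheet: data/measurements.csv   # or use the measurement sheet instead

global_args:
  veog_labels: [VEOG]       # channels used for blink detection
  vertex_labels: [Cz]       # shown in the blink-ERP QC figure
  event_code_map:           # BDF trigger code -> condition label
    1: std_short
    2: std_long
    3: dev_short
    4: dev_long

pipes:
  - id: "1"
    step_sets:
      - id: 1_load          # prepare: reference, blink events, filter, ICA
        save: true          # persist state so later pipes / reruns can start here
        steps:
          - op: rereference
            args: {scheme: average}
          - op: detect_blink_events
          - op: highpass_filter
            args: {cutoff_hz: 1.0, transition_hz: 1.0}
          - op: ica_decompose
      - id: 2_artifact_correction
        steps:
          - op: peek_data             # snapshot BEFORE correction
            args: {n_segments: 4, seg_len_s: 5.0, tag: pre}
          - op: detect_blink_ics      # template-match ICs to the blink waveform
          - op: filter_blink_ics      # correct them by high-pass filtering
          - op: detect_bad_channels_variance
            args: {bounds: [-5, 2.5]}
          - op: reject_channels       # spherical-spline interpolation
            args: {interpolate: true}
          - op: peek_data             # snapshot AFTER correction (same latencies)
            args: {n_segments: 4, seg_len_s: 5.0, tag: post}
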