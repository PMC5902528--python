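# Data-driven parameter selection: sweep the variance-detector bounds over
# 1..6 MAD in steps of 0.2, pick the outcome curve's inflection point, and
# inject the selected value into the following detector call.
#   eegpipe simulate --out examples/data --subjects 2 --duration 60 --seed 1
#   eegpipe run --config examples/sweep.yaml

project_root: output_sweep
seed: 42

measurements: {dir: data, pattern: "*.bdf"}

global_args:
  veog_labels: [VEOG]
  event_code_map: {1: std_short, 2: std_long, 3: dev_short, 4: dev_long}

pipes:
  - id: "1"
    step_sets:
      - id: 1_load
        steps:
          - op: rereference
          - op: detect_blink_events
          - op: highpass_filter
          - op: ica_decompose

  - id: "2"
    sources: ["1#1_load"]
    step_sets:
      - id: 2_sweep
        steps:
          - op: detect_blink_ics
          - op: filter_blink_ics
          - op: sweep                      # evaluates the grid on a data copy
            args:
              target_op: detect_bad_channels_variance
              sweep_param: bounds          # scalar t expands to [-t, +t]
              values: [1.0, 1.2, 1.4, 1.6, 1.8, 2.0, 2.2, 2.4, 2.6, 2.8,
                       3.0, 3.2, 3.4, 3.6, 3.8, 4.0, 4.2, 4.4, 4.6, 4.8,
                       5.0, 5.2, 5.4, 5.6, 5.8, 6.0]
          - op: detect_bad_channels_variance   # receives the selected bounds
          - op: reject_channels
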