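# Demo pipeline run: a small single-session cohort, all stages.
seed: 7
out_dir: optiongen_demo_out
simulate:
  design: single_session
  n_agents: 8
n_resample: 200
p_norm: 2
smooth: false
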