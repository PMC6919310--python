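dgm_kind: joint_regular_visits
lambda: 0.05
gamma_assoc: 3.0
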