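dgm_kind: joint
lambda: 1.00
gamma_assoc: 0.0
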