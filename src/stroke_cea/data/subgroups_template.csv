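label,hr_mean,hr_low,hr_high
Overall,0.83,0.71,0.96
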