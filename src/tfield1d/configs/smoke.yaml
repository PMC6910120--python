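# One-iteration smoke configuration.
mode: no_signal
J: [10]
fwhm: [20]
Q: 101
iterations: 1
design: one-sample
seed: 0
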