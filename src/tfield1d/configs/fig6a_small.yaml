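# Scaled-down signal-breadth sweep: FDR threshold vs pulse breadth sigma.
mode: with_signal
J: [10]
fwhm: [20]
sigma: [1, 2, 3, 5, 10, 15, 20]
amp: [2]
q: 50
Q: 101
iterations: 1000
design: one-sample
seed: 0
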