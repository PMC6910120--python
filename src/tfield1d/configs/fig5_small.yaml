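# Scaled-down no-signal grid: mean RFT/FDR thresholds vs sample size and smoothness.
mode: no_signal
J: [5, 10, 15, 25, 50]
fwhm: [10, 20, 30]
Q: 101
iterations: 1000
design: one-sample
seed: 0
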