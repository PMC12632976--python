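# Second-chromosome visible-marker map used for crossover scoring,
# tip of 2L to a marker across the centromere on 2R.
chromosome_label: "2L-2R"
loci: [net, dpp, dpy, b, pr, cn]
# control genetic lengths (cM) of the five intervals, usable as
# interval weights for simulation after normalisation
control_interval_cm: [4.8, 6.2, 30.3, 9.0, 2.4]
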