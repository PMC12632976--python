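# Moment calibration (mean, SD, N) for the per-nucleus count generator:
# gamma-H2Av focus counts and centromere (CID) cluster counts per
# genotype x germarium region.
gH2Av:
  control:
    "2A": {mean: 12.3, sd: 4.7, n: 32}
    "2B": {mean: 0.6, sd: 1.2, n: 29}
    "3": {mean: 0.0, sd: 0.0, n: 17}
  cpsf5_rnai:
    "2A": {mean: 11.6, sd: 3.5, n: 26}
    "2B": {mean: 9.2, sd: 4.8, n: 13}
    "3": {mean: 7.1, sd: 5.3, n: 14}
CID_clusters:
  control:
    "2A": {mean: 1.5, sd: 0.6, n: 48}
    "2B": {mean: 1.7, sd: 0.5, n: 26}
    "3": {mean: 1.8, sd: 0.7, n: 15}
    "mid-prophase": {mean: 1.9, sd: 0.7, n: 33}
  cpsf5_rnai:
    "2A": {mean: 2.3, sd: 0.9, n: 16}
    "2B": {mean: 2.6, sd: 0.9, n: 17}
    "3": {mean: 2.4, sd: 0.9, n: 9}
    "mid-prophase": {mean: 2.5, sd: 1.2, n: 31}
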