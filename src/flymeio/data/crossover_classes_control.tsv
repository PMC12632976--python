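k	count
0	879
1	779
2	62
3	1
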