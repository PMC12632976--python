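k	count
0	1131
1	569
2	80
3	2
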