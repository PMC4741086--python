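k	f_k
1	8025
2	605
3	129
4	41
5	16
6	8
7	4
8	2
9	1
10	1
11	1
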