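k	f_k
1	7986
2	518
3	129
4	50
5	24
6	12
7	7
8	5
9	3
10	2
11	1
12	1
13	1
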