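id,A,B,C,D
1,5,4,4,2
2,5,5,4,1
3,5,4,5,1
4,4,5,5,2
5,5,4,4,3
6,4,4,4,2
7,5,5,4,1
8,5,4,4,1
9,3,4,5,1
10,5,4,4,3
11,5,5,4,2
12,4,4,5,1
13,4,4,4,1
14,4,4,5,2
15,5,5,4,3
16,4,4,4,2
17,4,5,4,1
18,3,3,4,3
19,5,5,3,2
20,5,5,4,1
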