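category,before,after
0 to 5,35,7
6 to 9,16,6
10 to 14,20,17
15 to 19,15,25
20 to 25,3,22
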