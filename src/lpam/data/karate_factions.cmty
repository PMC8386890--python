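# two-faction split (Mr. Hi / Officer)
0 1 2 3 4 5 6 7 8 10 11 12 13 16 17 19 21
9 14 15 18 20 22 23 24 25 26 27 28 29 30 31 32 33
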