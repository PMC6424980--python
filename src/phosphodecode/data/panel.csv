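label,bitstring
0P,0000000
3Pa,1000101
3Pb,0100101
3Pc,0010101
3Pd,0001101
3Pe,1110000
3Pf,0000111
3Pg,0101100
3Ph,1010100
3Pi,0101001
3Pj,1100010
3Pk,1010010
4P,0001111
5P,1111100
6P,0111111
7P,1111111
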