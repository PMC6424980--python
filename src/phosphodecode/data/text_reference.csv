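label,arr1_binding,ctail_release,ternary
0P,weak,no,low
3Pa,tight,yes,robust
3Pb,tight,yes,robust
3Pc,tight,yes,robust
3Pd,tight,yes,robust
3Pe,weak,no,low
3Pf,weak,no,low
3Pg,weak,no,moderate
3Ph,weak,no,low
3Pi,weak,no,moderate
3Pj,weak,no,low
3Pk,weak,no,low
4P,tight,yes,robust
5P,weak,no,moderate
6P,tight,yes,robust
7P,tight,yes,robust
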