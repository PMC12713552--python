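cohort,minferet_min_um,minferet_max_um
0-3 months,2,120
4-6 months,2,120
7-9 months,2,120
10-12 months,2,120
1 year,2,120
2 years,2,120
3 years,2,120
4 years,2,120
5 years,2,120
6 years,2,120
7 years,2,120
8 years,2,120
9 years,2,120
10-12 years,2,120
13-15 years,2,120
16-18 years,2,120
19-21 years,2,120
22-25 years,2,120
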