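cohort,sex,n_fibers,n_biopsies,mean_um,sd_um,median_um
0-3 months,female,216394,9,11.56,5.32,10.87
0-3 months,male,463689,12,11.87,7.20,10.51
4-6 months,female,227401,5,15.68,6.71,15.23
4-6 months,male,343744,9,14.64,7.27,13.71
7-9 months,female,290784,6,13.45,5.15,13.04
7-9 months,male,233892,7,18.12,10.99,14.65
10-12 months,female,217103,6,16.65,8.81,15.30
10-12 months,male,5913,1,14.47,9.48,12.22
1 year,female,532258,11,15.33,7.52,14.26
1 year,male,558375,14,15.57,8.26,14.75
2 years,female,431735,13,20.67,7.83,19.16
2 years,male,445956,11,22.15,8.38,21.04
3 years,female,230798,14,23.48,7.51,23.01
3 years,male,182853,11,23.45,8.47,22.63
4 years,female,119504,9,26.54,13.47,23.81
4 years,male,251069,10,27.26,11.13,26.74
5 years,female,50299,5,36.08,14.03,33.69
5 years,male,104767,12,29.92,10.56,28.46
6 years,female,75203,9,35.00,13.14,32.75
6 years,male,52527,7,31.42,13.81,28.04
7 years,female,37328,3,34.05,12.60,31.64
7 years,male,71848,8,33.24,11.40,32.27
8 years,female,44260,5,34.10,12.85,32.98
8 years,male,100415,9,30.87,10.23,30.24
9 years,female,51771,9,36.33,13.89,35.73
9 years,male,49938,6,34.88,12.96,33.52
10-12 years,female,52807,11,41.91,12.89,40.74
10-12 years,male,125969,15,37.80,11.85,36.08
13-15 years,female,36294,11,51.83,15.55,51.24
13-15 years,male,47736,12,49.18,15.92,47.25
16-18 years,female,70900,15,48.22,14.30,46.55
16-18 years,male,73267,19,50.84,14.46,50.29
19-21 years,female,40037,12,47.49,11.67,46.78
19-21 years,male,28637,10,51.88,17.07,50.69
22-25 years,female,46639,12,49.54,12.83,49.00
22-25 years,male,38120,11,58.19,17.46,58.94
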