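cohort,sex,level,mean_um,sd_um,p_value
0-3 months,female,5,6.09,0.69,0.96
0-3 months,female,25,8.66,1.28,0.81
0-3 months,female,50,10.77,1.60,0.74
0-3 months,female,75,13.15,2.13,0.63
0-3 months,female,95,19.54,5.98,0.38
0-3 months,male,5,6.14,0.78,0.96
0-3 months,male,25,9.19,2.39,0.81
0-3 months,male,50,11.66,3.01,0.74
0-3 months,male,75,14.72,3.86,0.63
0-3 months,male,95,23.46,8.17,0.38
4-6 months,female,5,6.41,1.43,0.48
4-6 months,female,25,10.08,2.03,0.70
4-6 months,female,50,14.07,1.89,0.94
4-6 months,female,75,18.23,1.15,0.85
4-6 months,female,95,28.46,3.87,0.68
4-6 months,male,5,7.39,1.25,0.48
4-6 months,male,25,11.15,2.42,0.70
4-6 months,male,50,23.80,3.19,0.94
4-6 months,male,75,17.48,4.94,0.85
4-6 months,male,95,30.76,17.52,0.68
7-9 months,female,5,6.68,0.69,0.07
7-9 months,female,25,10.53,1.46,0.03
7-9 months,female,50,13.78,2.44,0.06
7-9 months,female,75,16.84,3.81,0.07
7-9 months,female,95,22.55,6.66,0.05
7-9 months,male,5,9.23,2.26,0.07
7-9 months,male,25,16.61,6.58,0.03
7-9 months,male,50,20.24,7.59,0.06
7-9 months,male,75,24.11,9.24,0.07
7-9 months,male,95,33.52,14.97,0.05
10-12 months,female,5,8.64,2.06,0.23
10-12 months,female,25,13.58,3.26,0.27
10-12 months,female,50,16.36,3.44,0.54
10-12 months,female,75,19.68,4.12,0.88
10-12 months,female,95,29.98,9.35,0.97
10-12 months,male,5,5.41,,0.23
10-12 months,male,25,7.56,,0.27
10-12 months,male,50,12.22,,0.54
10-12 months,male,75,18.52,,0.88
10-12 months,male,95,30.35,,0.97
1 year,female,5,6.48,0.84,0.86
1 year,female,25,12.40,2.75,0.84
1 year,female,50,16.20,3.67,0.94
1 year,female,75,19.52,4.24,0.96
1 year,female,95,28.36,7.06,0.82
1 year,male,5,6.66,1.57,0.86
1 year,male,25,11.99,2.87,0.84
1 year,male,50,16.02,4.16,0.94
1 year,male,75,19.67,4.53,0.96
1 year,male,95,29.30,7.47,0.82
2 years,female,5,12.68,1.96,0.73
2 years,female,25,17.18,3.41,0.61
2 years,female,50,20.62,4.12,0.64
2 years,female,75,24.61,5.17,0.67
2 years,female,95,35.18,10.52,0.56
2 years,male,5,13.03,1.57,0.73
2 years,male,25,18.22,3.12,0.61
2 years,male,50,21.79,3.64,0.64
2 years,male,75,25.89,3.83,0.67
2 years,male,95,37.06,7.71,0.56
3 years,female,5,13.40,2.14,0.99
3 years,female,25,18.82,2.60,0.91
3 years,female,50,22.93,2.58,0.83
3 years,female,75,27.18,2.68,0.91
3 years,female,95,37.37,5.77,0.55
3 years,male,5,13.41,2.36,0.99
3 years,male,25,18.59,3.59,0.91
3 years,male,50,22.38,3.67,0.83
3 years,male,75,26.85,3.21,0.91
3 years,male,95,39.81,9.65,0.55
4 years,female,5,12.65,3.28,0.64
4 years,female,25,19.88,5.59,0.95
4 years,female,50,26.67,8.28,0.64
4 years,female,75,33.67,11.11,0.42
4 years,female,95,48.63,15.10,0.38
4 years,male,5,13.20,2.94,0.64
4 years,male,25,20.02,5.09,0.95
4 years,male,50,25.34,5.87,0.64
4 years,male,75,30.94,6.46,0.42
4 years,male,95,44.58,9.98,0.38
5 years,female,5,19.01,1.89,0.56
5 years,female,25,29.23,7.92,0.07
5 years,female,50,36.49,11.69,0.05
5 years,female,75,44.34,13.93,0.021
5 years,female,95,61.80,12.31,0.009
5 years,male,5,18.24,2.40,0.56
5 years,male,25,24.32,3.77,0.07
5 years,male,50,29.93,6.60,0.05
5 years,male,75,35.35,8.25,0.021
5 years,male,95,47.58,9.84,0.009
6 years,female,5,19.62,2.99,0.57
6 years,female,25,27.89,4.84,0.46
6 years,female,50,34.39,6.55,0.49
6 years,female,75,41.66,9.70,0.96
6 years,female,95,56.95,13.35,0.99
6 years,male,5,18.91,4.26,0.57
6 years,male,25,26.02,6.66,0.46
6 years,male,50,33.56,11.42,0.49
6 years,male,75,41.49,16.96,0.96
6 years,male,95,56.88,21.90,0.99
7 years,female,5,18.51,2.64,0.70
7 years,female,25,28.52,4.32,0.67
7 years,female,50,36.19,7.62,0.41
7 years,female,75,42.88,10.21,0.42
7 years,female,95,56.19,16.05,0.76
7 years,male,5,19.17,2.52,0.70
7 years,male,25,27.06,4.36,0.67
7 years,male,50,32.71,4.59,0.41
7 years,male,75,38.94,5.12,0.42
7 years,male,95,54.13,10.75,0.76
8 years,female,5,17.32,1.20,0.93
8 years,female,25,25.14,2.15,0.86
8 years,female,50,33.26,3.32,0.50
8 years,female,75,40.56,4.57,0.44
8 years,female,95,54.83,8.59,0.31
8 years,male,5,17.45,1.85,0.93
8 years,male,25,24.65,4.37,0.86
8 years,male,50,30.92,4.45,0.50
8 years,male,75,37.40,4.67,0.44
8 years,male,95,49.08,8.67,0.31
9 years,female,5,17.88,2.55,0.73
9 years,female,25,28.30,8.69,0.32
9 years,female,50,37.32,9.65,0.21
9 years,female,75,45.85,10.62,0.24
9 years,female,95,60.28,11.79,0.77
9 years,male,5,17.41,1.19,0.73
9 years,male,25,25.63,3.50,0.32
9 years,male,50,33.25,2.72,0.21
9 years,male,75,41.32,2.13,0.24
9 years,male,95,58.69,4.08,0.77
10-12 years,female,5,23.61,2.93,0.59
10-12 years,female,25,31.68,4.64,0.67
10-12 years,female,50,40.04,5.54,0.47
10-12 years,female,75,48.42,6.90,0.41
10-12 years,female,95,64.66,9.38,0.22
10-12 years,male,5,23.07,2.82,0.59
10-12 years,male,25,30.82,5.71,0.67
10-12 years,male,50,38.82,7.11,0.47
10-12 years,male,75,46.04,7.68,0.41
10-12 years,male,95,59.56,9.52,0.22
13-15 years,female,5,28.38,2.52,0.20
13-15 years,female,25,38.54,6.36,0.84
13-15 years,female,50,47.90,6.83,0.68
13-15 years,female,75,56.90,7.01,0.54
13-15 years,female,95,71.25,6.22,0.44
13-15 years,male,5,29.71,4.86,0.20
13-15 years,male,25,28.97,8.50,0.84
13-15 years,male,50,46.82,9.98,0.68
13-15 years,male,75,55.04,11.21,0.54
13-15 years,male,95,68.02,12.11,0.44
16-18 years,female,5,28.58,1.94,0.62
16-18 years,female,25,38.98,5.97,0.18
16-18 years,female,50,47.48,7.67,0.026
16-18 years,female,75,55.89,9.03,0.014
16-18 years,female,95,69.20,11.88,0.07
16-18 years,male,5,29.00,2.33,0.62
16-18 years,male,25,41.32,4.32,0.18
16-18 years,male,50,52.26,5.28,0.026
16-18 years,male,75,62.14,6.69,0.014
16-18 years,male,95,75.45,7.79,0.07
19-21 years,female,5,30.05,2.46,0.16
19-21 years,female,25,39.78,4.62,0.90
19-21 years,female,50,47.44,6.25,0.11
19-21 years,female,75,54.72,7.55,0.007
19-21 years,female,95,66.43,8.79,0.002
19-21 years,male,5,28.52,2.47,0.16
19-21 years,male,25,40.06,7.45,0.90
19-21 years,male,50,51.66,8.86,0.11
19-21 years,male,75,63.14,8.68,0.007
19-21 years,male,95,80.33,8.05,0.002
22-25 years,female,5,30.51,3.08,0.25
22-25 years,female,25,40.81,5.54,0.67
22-25 years,female,50,48.41,6.28,0.05
22-25 years,female,75,56.06,7.06,0.001
22-25 years,female,95,68.32,7.32,<0.001
22-25 years,male,5,29.30,4.34,0.25
22-25 years,male,25,41.71,8.05,0.67
22-25 years,male,50,53.44,8.55,0.05
22-25 years,male,75,65.93,7.33,0.001
22-25 years,male,95,82.59,7.46,<0.001
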