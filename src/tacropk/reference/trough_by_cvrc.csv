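c_vrc,dose_mg,mean_ng_ml,sd_ng_ml
0.0,0.5,0.82,0.22
0.0,1.0,1.65,0.45
0.0,1.5,2.47,0.67
0.0,2.0,3.29,0.9
0.0,2.5,4.12,1.12
0.0,3.0,4.94,1.35
0.0,3.5,5.76,1.57
0.0,4.0,6.59,1.8
0.0,4.5,7.41,2.02
0.0,5.0,8.23,2.25
0.0,5.5,9.06,2.47
0.5,0.5,0.88,0.25
0.5,1.0,1.75,0.5
0.5,1.5,2.63,0.74
0.5,2.0,3.5,0.99
0.5,2.5,4.38,1.24
0.5,3.0,5.25,1.49
0.5,3.5,6.13,1.74
0.5,4.0,7.0,1.99
0.5,4.5,7.88,2.23
0.5,5.0,8.76,2.48
0.5,5.5,9.63,2.73
1.0,0.5,0.95,0.27
1.0,1.0,1.89,0.53
1.0,1.5,2.84,0.8
1.0,2.0,3.79,1.07
1.0,2.5,4.73,1.34
1.0,3.0,5.68,1.6
1.0,3.5,6.62,1.87
1.0,4.0,7.57,2.14
1.0,4.5,8.52,2.41
1.0,5.0,9.46,2.67
1.0,5.5,10.41,2.94
1.5,0.5,1.01,0.28
1.5,1.0,2.02,0.57
1.5,1.5,3.03,0.85
1.5,2.0,4.05,1.14
1.5,2.5,5.06,1.42
1.5,3.0,6.07,1.71
1.5,3.5,7.08,1.99
1.5,4.0,8.09,2.28
1.5,4.5,9.1,2.56
1.5,5.0,10.12,2.85
1.5,5.5,11.13,3.13
2.0,0.5,1.1,0.31
2.0,1.0,2.2,0.62
2.0,1.5,3.3,0.93
2.0,2.0,4.4,1.24
2.0,2.5,5.49,1.55
2.0,3.0,6.59,1.86
2.0,3.5,7.69,2.17
2.0,4.0,8.79,2.48
2.0,4.5,9.89,2.79
2.0,5.0,10.99,3.1
2.0,5.5,12.09,3.41
2.5,0.5,1.21,0.32
2.5,1.0,2.42,0.64
2.5,1.5,3.63,0.95
2.5,2.0,4.84,1.27
2.5,2.5,6.05,1.59
2.5,3.0,7.26,1.91
2.5,3.5,8.47,2.23
2.5,4.0,9.68,2.54
2.5,4.5,10.89,2.86
2.5,5.0,12.1,3.18
2.5,5.5,13.31,3.5
3.0,0.5,1.32,0.34
3.0,1.0,2.65,0.69
3.0,1.5,3.97,1.03
3.0,2.0,5.29,1.38
3.0,2.5,6.62,1.72
3.0,3.0,7.94,2.07
3.0,3.5,9.27,2.41
3.0,4.0,10.59,2.76
3.0,4.5,11.91,3.1
3.0,5.0,13.24,3.45
3.0,5.5,14.56,3.79
3.5,0.5,1.49,0.4
3.5,1.0,2.98,0.81
3.5,1.5,4.46,1.21
3.5,2.0,5.95,1.62
3.5,2.5,7.44,2.02
3.5,3.0,8.93,2.43
3.5,3.5,10.41,2.83
3.5,4.0,11.9,3.23
3.5,4.5,13.39,3.64
3.5,5.0,14.88,4.04
3.5,5.5,16.37,4.45
4.0,0.5,1.65,0.46
4.0,1.0,3.31,0.91
4.0,1.5,4.96,1.37
4.0,2.0,6.61,1.82
4.0,2.5,8.26,2.28
4.0,3.0,9.92,2.73
4.0,3.5,11.57,3.19
4.0,4.0,13.22,3.64
4.0,4.5,14.88,4.1
4.0,5.0,16.53,4.55
4.0,5.5,18.18,5.01
4.5,0.5,1.92,0.48
4.5,1.0,3.83,0.97
4.5,1.5,5.75,1.45
4.5,2.0,7.66,1.94
4.5,2.5,9.58,2.42
4.5,3.0,11.49,2.91
4.5,3.5,13.41,3.39
4.5,4.0,15.33,3.88
4.5,4.5,17.24,4.36
4.5,5.0,19.16,4.85
4.5,5.5,21.07,5.33
5.0,0.5,2.26,0.57
5.0,1.0,4.51,1.15
5.0,1.5,6.77,1.72
5.0,2.0,9.02,2.29
5.0,2.5,11.28,2.86
5.0,3.0,13.54,3.44
5.0,3.5,15.79,4.01
5.0,4.0,18.05,4.58
5.0,4.5,20.3,5.15
5.0,5.0,22.56,5.73
5.0,5.5,24.82,6.3
5.5,0.5,2.73,0.65
5.5,1.0,5.47,1.3
5.5,1.5,8.2,1.94
5.5,2.0,10.93,2.59
5.5,2.5,13.67,3.24
5.5,3.0,16.4,3.89
5.5,3.5,19.14,4.53
5.5,4.0,21.87,5.18
5.5,4.5,24.6,5.83
5.5,5.0,27.34,6.48
5.5,5.5,30.07,7.12
6.0,0.5,3.47,0.77
6.0,1.0,6.94,1.55
6.0,1.5,10.4,2.32
6.0,2.0,13.87,3.09
6.0,2.5,17.34,3.87
6.0,3.0,20.81,4.64
6.0,3.5,24.27,5.41
6.0,4.0,27.74,6.19
6.0,4.5,31.21,6.96
6.0,5.0,34.68,7.74
6.0,5.5,38.14,8.51
6.5,0.5,4.76,1.04
6.5,1.0,9.53,2.08
6.5,1.5,14.29,3.12
6.5,2.0,19.05,4.16
6.5,2.5,23.82,5.2
6.5,3.0,28.58,6.24
6.5,3.5,33.34,7.29
6.5,4.0,38.1,8.33
6.5,4.5,42.87,9.37
6.5,5.0,47.63,10.41
6.5,5.5,52.39,11.45
7.0,0.5,7.31,1.36
7.0,1.0,14.61,2.73
7.0,1.5,21.92,4.09
7.0,2.0,29.22,5.46
7.0,2.5,36.53,6.82
7.0,3.0,43.83,8.19
7.0,3.5,51.14,9.55
7.0,4.0,58.44,10.91
7.0,4.5,65.75,12.28
7.0,5.0,73.06,13.64
7.0,5.5,80.36,15.01
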