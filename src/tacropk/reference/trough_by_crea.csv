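crea,dose_mg,mean_ng_ml,sd_ng_ml
40,0.25,0.59,0.12
100,0.25,0.78,0.18
160,0.25,0.88,0.21
400,0.25,1.13,0.31
600,0.25,1.21,0.34
800,0.25,1.29,0.4
1000,0.25,1.31,0.42
1600,0.25,1.41,0.48
1800,0.25,1.45,0.49
2000,0.25,1.42,0.49
40,0.5,0.59,0.12
100,0.5,0.78,0.18
160,0.5,0.88,0.21
400,0.5,1.13,0.31
600,0.5,1.21,0.34
800,0.5,1.29,0.4
1000,0.5,1.31,0.42
1600,0.5,1.41,0.48
1800,0.5,1.45,0.49
2000,0.5,1.42,0.49
40,1.0,1.17,0.24
100,1.0,1.56,0.35
160,1.0,1.77,0.43
400,1.0,2.26,0.62
600,1.0,2.42,0.68
800,1.0,2.57,0.79
1000,1.0,2.63,0.84
1600,1.0,2.81,0.97
1800,1.0,2.9,0.99
2000,1.0,2.84,0.98
40,1.5,1.76,0.36
100,1.5,2.34,0.53
160,1.5,2.65,0.64
400,1.5,3.39,0.93
600,1.5,3.63,1.02
800,1.5,3.86,1.19
1000,1.5,3.94,1.26
1600,1.5,4.22,1.45
1800,1.5,4.35,1.48
2000,1.5,4.26,1.47
40,2.0,2.35,0.48
100,2.0,3.12,0.7
160,2.0,3.54,0.85
400,2.0,4.52,1.24
600,2.0,4.84,1.36
800,2.0,5.15,1.58
1000,2.0,5.25,1.68
1600,2.0,5.62,1.94
1800,2.0,5.79,1.97
2000,2.0,5.67,1.96
40,2.5,2.94,0.6
100,2.5,3.9,0.88
160,2.5,4.42,1.07
400,2.5,5.65,1.55
600,2.5,6.05,1.7
800,2.5,6.43,1.98
1000,2.5,6.56,2.09
1600,2.5,7.03,2.42
1800,2.5,7.24,2.46
2000,2.5,7.09,2.45
40,3.0,3.52,0.73
100,3.0,4.68,1.05
160,3.0,5.31,1.28
400,3.0,6.78,1.86
600,3.0,7.27,2.04
800,3.0,7.72,2.37
1000,3.0,7.88,2.51
1600,3.0,8.43,2.91
1800,3.0,8.69,2.96
2000,3.0,8.51,2.94
40,3.5,4.11,0.85
100,3.5,5.46,1.23
160,3.5,6.19,1.49
400,3.5,7.91,2.16
600,3.5,8.48,2.38
800,3.5,9.01,2.77
1000,3.5,9.19,2.93
1600,3.5,9.84,3.39
1800,3.5,10.14,3.45
2000,3.5,9.93,3.43
40,4.0,4.7,0.97
100,4.0,6.24,1.41
160,4.0,7.08,1.7
400,4.0,9.03,2.47
600,4.0,9.69,2.72
800,4.0,10.3,3.16
1000,4.0,10.5,3.35
1600,4.0,11.25,3.88
1800,4.0,11.59,3.94
2000,4.0,11.35,3.92
40,4.5,5.29,1.09
100,4.5,7.02,1.58
160,4.5,7.96,1.92
400,4.5,10.16,2.78
600,4.5,10.9,3.06
800,4.5,11.58,3.56
1000,4.5,11.82,3.77
1600,4.5,12.65,4.36
1800,4.5,13.04,4.43
2000,4.5,12.77,4.41
40,5.0,5.87,1.21
100,5.0,7.8,1.76
160,5.0,8.85,2.13
400,5.0,11.29,3.09
600,5.0,12.11,3.4
800,5.0,12.87,3.95
1000,5.0,13.13,4.19
1600,5.0,14.06,4.84
1800,5.0,14.49,4.93
2000,5.0,14.19,4.9
40,5.5,6.46,1.33
100,5.5,8.58,1.93
160,5.5,9.73,2.34
400,5.5,12.42,3.4
600,5.5,13.32,3.74
800,5.5,14.16,4.35
1000,5.5,14.44,4.61
1600,5.5,15.46,5.33
1800,5.5,15.94,5.42
2000,5.5,15.6,5.39
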