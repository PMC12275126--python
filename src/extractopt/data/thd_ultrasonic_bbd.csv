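run,ratio_ml_per_g,temperature_c,time_min,power_w,yield_pct,pred_rsm,pred_bp,pred_gaaco_bp
1,20,90,60,300,13.70,14.96,13.02,13.36
2,25,100,75,250,16.32,16.48,16.36,16.64
3,25,90,75,300,15.15,16.12,15.97,16.56
4,25,100,90,300,15.71,16.47,15.73,15.71
5,25,90,90,250,16.41,15.92,16.41,16.41
6,25,90,75,300,14.76,16.12,15.97,16.56
7,25,90,60,350,13.59,14.31,14.13,13.59
8,20,90,75,250,17.05,16.03,16.16,15.73
9,20,90,75,350,16.72,16.10,16.44,16.72
10,25,80,75,250,8.08,9.23,8.12,8.08
11,25,90,75,300,16.85,16.12,15.97,16.56
12,30,90,60,300,15.96,15.32,15.87,15.96
13,25,90,75,300,18.07,16.12,15.97,16.56
14,30,90,90,300,17.66,17.19,17.59,17.66
15,20,90,90,300,14.94,16.36,15.73,14.94
16,30,80,75,300,8.85,9.90,8.82,8.85
17,20,100,75,300,16.22,15.40,16.36,15.67
18,25,90,90,350,17.11,16.72,17.54,15.94
19,30,90,75,350,16.65,16.66,17.25,16.65
20,25,100,75,350,15.73,15.37,16.64,15.73
21,25,100,60,300,14.75,14.57,16.41,14.75
22,20,80,75,300,10.87,10.66,9.80,10.87
23,30,90,75,250,17.06,16.66,16.25,16.74
24,25,90,60,250,14.44,15.05,14.79,14.41
25,30,100,75,300,16.91,17.36,15.91,17.21
26,25,80,90,300,10.93,10.10,11.41,11.10
27,25,80,60,300,10.51,8.73,10.37,10.34
28,25,90,75,300,15.76,16.12,15.97,16.56
29,25,80,75,350,9.78,10.41,10.24,9.89
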