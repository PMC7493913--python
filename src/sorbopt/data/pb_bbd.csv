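# Pb(II) biosorption Box-Behnken experiment: 15 runs, 3 factors
# factors: pH in [4, 8]; temperature in [20, 40] C; dose in [0.5, 1.5] g/L
# response: Pb(II) removal efficiency, percent
run,pH_coded,temperature_coded,dose_coded,pH_actual,temperature_actual,dose_actual,response
1,1,1,0,8,40,1.0,83.71
2,1,0,-1,8,30,0.5,79.71
3,0,0,0,6,30,1.0,94.76
4,1,-1,0,8,20,1.0,90.39
5,0,1,1,6,40,1.5,93.25
6,0,-1,-1,6,20,0.5,84.70
7,-1,0,1,4,30,1.5,86.23
8,0,1,-1,6,40,0.5,79.41
9,0,0,0,6,30,1.0,94.81
10,0,-1,1,6,20,1.5,95.67
11,0,0,0,6,30,1.0,94.39
12,-1,1,0,4,40,1.0,71.15
13,-1,-1,0,4,20,1.0,74.20
14,-1,0,-1,4,30,0.5,64.88
15,1,0,1,8,30,1.5,91.46
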