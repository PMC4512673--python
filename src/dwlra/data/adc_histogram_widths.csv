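dataset,PA,AVG,LRA,NRA,LRA-b,AVG-b
v1-0503,27.25,30.62,27.54,22.36,23.78,26.58
v1-0515,31.05,28.85,23.58,20.53,19.31,24.69
v2-0521,54.25,55.09,44.01,63.29,42.00,53.69
v2-0528,62.04,56.12,48.15,61.49,45.62,54.24
v3-0524,56.73,67.85,65.79,67.59,62.94,64.72
v3-0528,71.82,70.71,58.64,64.25,57.18,68.55
v4-0611,32.07,32.92,30.54,25.99,26.79,28.15
v4-0614,38.30,33.94,33.85,28.27,29.53,29.61
v5-0731,32.40,32.68,33.60,29.41,29.81,28.88
v5-0809,32.59,31.06,34.34,28.94,30.09,27.01
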