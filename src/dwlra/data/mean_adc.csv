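dataset,PA,AVG,LRA,NRA,LRA-b,AVG-b
v1-0503,113.90,113.67,108.35,109.27,107.53,112.64
v1-0515,127.66,105.36,105.51,108.91,105.45,104.18
v2-0521,119.22,111.43,99.45,109.45,102.19,111.32
v2-0528,129.53,105.74,102.61,105.95,99.52,105.50
v3-0524,115.24,100.60,93.38,95.67,92.39,98.51
v3-0528,104.82,97.54,89.86,92.35,88.96,96.31
v4-0611,129.42,101.63,92.54,94.47,91.65,100.98
v4-0614,129.89,99.30,95.23,92.88,93.74,97.72
v5-0731,104.68,78.72,73.65,76.21,71.58,76.70
v5-0809,105.81,77.57,76.57,76.65,75.25,75.77
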