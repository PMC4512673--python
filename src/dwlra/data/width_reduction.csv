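dataset,LRA,NRA,LRA-b,AVG-b
v1-0503,13.38,20.91,19.28,15.20
v1-0515,16.62,20.26,21.43,14.92
v2-0521,33.13,-31.15,35.64,12.34
v2-0528,28.82,-25.13,32.68,14.40
v3-0524,16.59,5.93,25.34,20.37
v3-0528,39.51,29.52,41.59,17.34
v4-0611,12.28,20.20,19.13,17.06
v4-0614,2.47,18.78,16.73,16.58
v5-0731,-7.80,14.24,13.39,15.29
v5-0809,-14.64,11.27,7.70,15.33
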