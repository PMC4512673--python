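pair,PA,AVG,LRA,NRA,LRA-b,AVG-b
v1-0503-0515,11.39,7.58,2.65,0.33,1.95,7.80
v2-0521-0528,8.28,5.24,3.12,3.24,2.64,5.36
v3-0524-0528,9.47,3.08,3.84,3.53,3.78,2.25
v4-0611-0614,0.36,2.31,2.86,1.69,2.25,3.28
v5-0731-0809,1.07,1.47,3.88,0.57,4.99,1.21
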