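depth_lo_m,depth_hi_m,count
0.0,0.2,1
0.2,0.3,7
0.3,0.4,27
0.4,0.5,54
0.5,0.6,41
0.6,0.7,26
0.7,0.8,7
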