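treatment,source,stage,count,min_p,r2_min,r2_max
W,measured,HS,12,9.91E-05,9.42,14.56
W,measured,FL,46,1.96E-04,9.61,13.01
W,measured,GF,14,1.87E-04,10.04,13.56
W,predicted,HS,12,1.26E-04,9.65,13.42
W,predicted,FL,52,7.63E-06,9.22,18.98
W,predicted,GF,45,1.05E-05,9.44,18.24
D,measured,HS,10,2.87E-04,9.31,11.98
D,measured,FL,8,1.51E-04,10.12,15.83
D,measured,GF,12,2.96E-04,9.83,13.02
D,predicted,HS,32,1.08E-04,9.14,12.68
D,predicted,FL,42,6.77E-05,7.58,14.03
D,predicted,GF,23,5.77E-06,10.04,19.58
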