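treatment,band,stage,reflectance_pct
W,red,HS,7.68
W,red,FL,7.65
W,red,GF,5.85
W,rededge,HS,34.03
W,rededge,FL,33.11
W,rededge,GF,27.22
W,nir,HS,56.84
W,nir,FL,55.14
W,nir,GF,37.47
W,green,HS,15.93
W,green,FL,15.06
W,green,GF,7.7
W,blue,HS,6.74
W,blue,FL,6.38
W,blue,GF,4.54
D,red,HS,7.88
D,red,FL,7.7
D,red,GF,6.95
D,rededge,HS,33.74
D,rededge,FL,31.42
D,rededge,GF,27.88
D,nir,HS,55.4
D,nir,FL,52.33
D,nir,GF,34.93
D,green,HS,15.82
D,green,FL,14.81
D,green,GF,8.31
D,blue,HS,6.7
D,blue,FL,6.38
D,blue,GF,4.94
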