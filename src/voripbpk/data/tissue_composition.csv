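organ,f_water,f_neutral_lipid,f_phospholipid
lung,0.811,0.0030,0.0090
brain,0.753,0.0392,0.0533
heart,0.758,0.0115,0.0166
kidney,0.783,0.0207,0.0162
liver,0.751,0.0348,0.0252
spleen,0.788,0.0201,0.0198
gut_wall,0.718,0.0138,0.0303
stomach,0.718,0.0138,0.0303
pancreas,0.641,0.0403,0.0090
muscle,0.760,0.0100,0.0072
adipose,0.144,0.8530,0.0016
skin,0.718,0.0284,0.0111
bone,0.417,0.0740,0.0011
gonads,0.800,0.0100,0.0120
plasma,0.945,0.0035,0.00225
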