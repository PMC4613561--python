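metabolite,low_ppm,high_ppm
lipid,0.88,0.92
lipid,1.26,1.34
lipid,5.30,5.36
isoleucine,0.93,0.95
isoleucine,1.00,1.02
leucine,0.95,0.97
valine,0.98,1.00
valine,1.03,1.05
lactate,1.31,1.35
lactate,4.09,4.13
threonine,4.24,4.26
alanine,1.46,1.50
lysine,1.70,1.74
lysine,3.01,3.04
arginine,1.66,1.70
arginine,3.22,3.26
acetate,1.90,1.93
glutamate,2.06,2.10
glutamate,2.32,2.36
methionine,2.12,2.14
methionine,2.63,2.65
glutamine,2.13,2.16
glutamine,2.43,2.47
aspartate,2.66,2.70
aspartate,2.78,2.82
glutathione,2.16,2.18
glutathione,2.53,2.57
glutathione,2.93,2.97
choline,3.19,3.21
phosphocholine,3.21,3.23
glycerophosphocholine,3.22,3.24
taurine,3.24,3.28
taurine,3.40,3.44
scyllo-inositol,3.34,3.36
myo-inositol,3.52,3.56
myo-inositol,3.60,3.63
myo-inositol,4.05,4.07
glycine,3.55,3.57
phosphoethanolamine,3.97,3.99
inosine,6.09,6.11
inosine,8.23,8.25
inosine,8.33,8.35
tyrosine,6.88,6.92
tyrosine,7.17,7.21
phenylalanine,7.31,7.34
phenylalanine,7.41,7.44
histidine,7.05,7.09
histidine,7.80,7.84
fumarate,6.51,6.53
uracil,5.79,5.81
uracil,7.53,7.55
guanosine,5.91,5.93
guanosine,8.01,8.03
hypoxanthine,8.18,8.22
xanthine,7.88,7.90
formate,8.45,8.47
acetamide,1.99,2.01
succinate,2.40,2.42
citrate,2.52,2.56
citrate,2.64,2.68
uridine,5.89,5.91
uridine,7.86,7.88
U1,7.65,7.67
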