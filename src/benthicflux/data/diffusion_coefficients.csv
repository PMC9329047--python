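species,m0,m1,note
Fe2+,3.31,0.150,Boudreau (1997) linear fit for ferrous iron
Mn2+,3.18,0.155,Boudreau (1997) linear fit for manganous manganese
HS-,10.4,0.273,Boudreau (1997) linear fit for bisulfide
H2S,10.9,0.360,approximate linear fit to free-solution H2S data
O2,11.7,0.344,approximate linear fit to free-solution O2 data
HAsO4--,3.70,0.148,linear fit anchored to 7.40e-6 cm2 s-1 at 25 C (arsenate HAsO4 2-)
H2AsO4-,4.52,0.181,linear fit anchored to 9.05e-6 cm2 s-1 at 25 C (arsenate H2AsO4-)
H3AsO3,5.50,0.220,linear fit anchored to 1.10e-5 cm2 s-1 at 25 C (arsenite)
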