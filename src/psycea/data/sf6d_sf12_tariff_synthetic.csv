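# SF-6D (SF-12 classification) additive-decrement utility tariff, version synthetic-1.
# SYNTHETIC stand-in coefficient set: it reproduces the structure of the published
# UK valuation model (utility = 1 - per-dimension level decrements - a single MOST
# penalty applied once when any dimension is at its most severe level; decrements
# monotone within each dimension; level 1 carries no decrement) but the decrement
# values are not the published estimates. Alternative tariff files with the same
# layout can be supplied anywhere this preset is accepted.
dimension,level,decrement
pf,2,0.012
pf,3,0.045
rl,2,0.063
rl,3,0.063
rl,4,0.063
sf,2,0.063
sf,3,0.066
sf,4,0.081
sf,5,0.093
pain,2,0.042
pain,3,0.042
pain,4,0.065
pain,5,0.102
mh,2,0.059
mh,3,0.059
mh,4,0.113
mh,5,0.134
vit,2,0.078
vit,3,0.078
vit,4,0.078
vit,5,0.106
_most,1,0.077
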