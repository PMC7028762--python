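# SF-12 (version 1) norm-based component summary scoring weights, US 1998 general
# population norms. One row per (component, item, response) indicator weight in the
# item's natural questionnaire coding; the reference (best) response of each item has
# weight 0 and is omitted. `_constant` rows carry the regression intercepts.
component,item,response,weight
pcs,_constant,0,56.57706
mcs,_constant,0,60.75781
pcs,gh1,2,-1.31872
pcs,gh1,3,-3.02396
pcs,gh1,4,-5.56461
pcs,gh1,5,-8.37399
mcs,gh1,2,-0.06064
mcs,gh1,3,0.03482
mcs,gh1,4,-0.16891
mcs,gh1,5,-1.71175
pcs,pf02,2,-3.45555
pcs,pf02,1,-7.23216
mcs,pf02,2,1.86840
mcs,pf02,1,3.93115
pcs,pf04,2,-2.73557
pcs,pf04,1,-6.24397
mcs,pf04,2,1.43103
mcs,pf04,1,2.68282
pcs,rp2,1,-4.61617
mcs,rp2,1,1.44060
pcs,rp3,1,-5.51747
mcs,rp3,1,1.66968
pcs,re2,1,3.04365
mcs,re2,1,-6.82672
pcs,re3,1,2.32091
mcs,re3,1,-5.69921
pcs,bp2,2,-3.80130
pcs,bp2,3,-6.50522
pcs,bp2,4,-8.38063
pcs,bp2,5,-11.25544
mcs,bp2,2,0.90384
mcs,bp2,3,1.49384
mcs,bp2,4,1.76691
mcs,bp2,5,1.48619
pcs,mh3,2,0.66514
pcs,mh3,3,1.36689
pcs,mh3,4,2.37241
pcs,mh3,5,2.90426
pcs,mh3,6,3.46638
mcs,mh3,2,-1.94949
mcs,mh3,3,-4.09842
mcs,mh3,4,-6.31121
mcs,mh3,5,-7.92717
mcs,mh3,6,-10.19085
pcs,vt2,2,-0.42251
pcs,vt2,3,-1.14387
pcs,vt2,4,-1.61850
pcs,vt2,5,-2.02168
pcs,vt2,6,-2.44706
mcs,vt2,2,-0.92057
mcs,vt2,3,-1.65178
mcs,vt2,4,-3.29805
mcs,vt2,5,-4.88962
mcs,vt2,6,-6.02409
pcs,mh4,1,4.61446
pcs,mh4,2,3.41593
pcs,mh4,3,2.34247
pcs,mh4,4,1.28044
pcs,mh4,5,0.41188
mcs,mh4,1,-16.15395
mcs,mh4,2,-10.77911
mcs,mh4,3,-8.09914
mcs,mh4,4,-4.59055
mcs,mh4,5,-1.95934
pcs,sf2,1,-0.33682
pcs,sf2,2,-0.94342
pcs,sf2,3,-0.18043
pcs,sf2,4,0.11038
mcs,sf2,1,-6.29724
mcs,sf2,2,-8.26066
mcs,sf2,3,-5.63286
mcs,sf2,4,-3.13896
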