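site_id,island,status_local,status_10km,status_60km,dist_port_km,dist_freshwater,dist_pollution,algae_cover,wave_exposure,traffic,substrate,aquaculture,nis_prop,n_native,richness,simpson
M-PP,Moorea,1,0.252,1.575,0.2,0.1,0.03,0.1,4,4,5,0,0.4,3,0.8764,0.5195
M-Pa,Moorea,1,0.5355,1.575,0.3,0.05,0.1,0.4,3,3,2,0,0.17,5,1.095,0.7761
M-Th,Moorea,1,0.567,1.575,0.5,1,0.05,0.3,3,2,3,0,0.2,4,0.8784,0.5991
M-Fa,Moorea,1,0.252,1.575,2,0.1,1,0.2,3,1,3,0,0.17,5,1.117,0.6157
M-Vn,Moorea,1,0.189,1.575,0.2,0.5,0.3,0.3,3,3,5,0,0.2,4,0.9294,0.7149
M-Vr,Moorea,1,0.0945,1.575,0,0.8,0.8,0.1,4,5,5,0,0.17,10,2.34,0.7248
M-Ti,Moorea,5,0.315,1.575,6,1,0.02,0.1,2,3,5,0.079365079,0,1,0,0
M-At,Moorea,3,0.36225,1.575,0.2,0.8,1,0.1,5,1,1,0,0,3,0.4402,0.2743
M-Hu,Moorea,5,0.7875,1.575,3,1,0.5,0.1,2,2,5,0,0,2,0.2191,0.02083
M-Ha,Moorea,3,0.3465,1.575,3,0.2,0.5,0.1,3,1,1,0,0,2,0.2191,0.4342
M-Mh,Moorea,2,0.315,1.575,0.2,0.02,0.1,0.1,4,3,4,0,0,4,0.6635,0.4872
M-Te,Moorea,5,0.36225,1.575,0.3,1,0.1,0.1,4,3,5,0,0,3,0.4382,0.534
M-Ma,Moorea,5,0.42525,1.575,0.3,1,0.02,0.3,5,2,5,0,0,3,0.4456,0.4668
M-EB,Moorea,2,0.4095,1.575,2,1,0.2,0.5,3,4,4,0,0,9,1.842,0.6364
M-Op,Moorea,3,0.441,1.575,0.2,0.3,0.1,0.1,1,1,1,0.158730159,0,5,0.8764,0.5934
M-Af,Moorea,3,0.3465,1.575,0.05,0.1,0.03,0.1,5,3,4,0,0,4,0.6573,0.6287
V-CI,VancouverEast,1,0.0282,0.705,2.2,0.5,0.02,0.7,3,5,3,5,0.5,1,0.2612,0.1511
V-Cr,VancouverEast,1,0.0141,0.705,1.6,0,0.1,0.9,1,4,3,1.19047619,0.4,3,0.9894,0.4974
V-FB,VancouverEast,1,0.0141,0.705,2.9,0,0.8,0.6,2,2,4,3.571428571,0.6,4,2.031,0.7388
V-NB,VancouverEast,1,0.02115,0.705,2.3,1,0.5,0.1,2,3,4,1.904761905,0.29,5,1.347,0.7753
V-PI,VancouverEast,1,0.0141,0.705,4.2,0,0.5,0.2,2,4,1,0.476190476,0.125,7,1.642,0.6215
V-Ld,VancouverEast,3,0.0846,0.705,6.8,0.9,0.1,0.9,1,2,3,1.19047619,0,3,0.4692,0.6374
V-Sd,VancouverEast,2,0.0141,0.705,0.34,0,0.5,0.3,1,4,2,0.476190476,0,8,1.683,0.5229
V-Vi,VancouverEast,3,0.0846,0.705,1.1,0,0.1,0.8,4,3,4,0,0,6,1.103,0.653
V-Sk,VancouverWest,1,0.6,5,0,0,0.1,0.5,1,5,4,0,0.111,8,1.791,0.6289
V-CB,VancouverWest,3,1,5,30,1,0.5,0.1,5,2,2,0,0,8,1.571,0.691
V-Bf,VancouverWest,5,5,5,0,0,0.1,0.9,3,2,3,1.666666667,0,6,1.106,0.7275
V-PA,VancouverWest,1,0.2,5,0,0.1,0.3,0.9,1,1,5,0,0,2,0.2556,0.2423
V-SB,VancouverWest,1,0.1,5,9.3,0.53,0.5,0.5,5,2,2,1.666666667,0.1,9,2.015,0.7781
V-LB,VancouverWest,1,0.9,5,18.7,0.95,1,0.5,5,1,1,0,0.111,8,1.626,0.4825
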