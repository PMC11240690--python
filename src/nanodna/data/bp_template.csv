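# idealized A-T base-pair template, one helix repeat; units nm
# helix axis +z, base plane z=0; see docs/methods.md
name,element,x_nm,y_nm,z_nm,strand,moiety,base
L.C1p,C,0.267854,0.525694,0.000000,labeled,sugar_phosphate,
L.C2p,C,0.396983,0.519442,0.072046,labeled,sugar_phosphate,
L.C3p,C,0.458181,0.654136,0.067999,labeled,sugar_phosphate,
L.C4p,C,0.366874,0.743634,-0.006548,labeled,sugar_phosphate,
L.O4p,O,0.249246,0.664252,-0.048574,labeled,sugar_phosphate,
L.C5p,C,0.257697,0.816473,0.070125,labeled,sugar_phosphate,
L.O5p,O,0.145781,0.889718,0.120712,labeled,sugar_phosphate,
L.P,P,0.020040,0.957387,0.192893,labeled,sugar_phosphate,
L.OP1,O,-0.078981,1.057923,0.148269,labeled,sugar_phosphate,
L.OP2,O,0.159578,0.936370,0.148269,labeled,sugar_phosphate,
L.O3p,O,0.464834,0.727258,-0.054712,labeled,sugar_phosphate,
L.H1p,H,0.184623,0.492453,0.062037,labeled,sugar_phosphate,
L.H2p,H,0.385324,0.482736,0.174015,labeled,sugar_phosphate,
L.H2pp,H,0.463134,0.443090,0.031114,labeled,sugar_phosphate,
L.H3p,H,0.480441,0.692087,0.167725,labeled,sugar_phosphate,
L.H4p,H,0.338525,0.831189,0.051859,labeled,sugar_phosphate,
L.H5p,H,0.181957,0.888849,0.040023,labeled,sugar_phosphate,
L.H5pp,H,0.360769,0.797740,0.040023,labeled,sugar_phosphate,
N.C1p,C,0.267854,-0.525694,0.000000,nonlabeled,sugar_phosphate,
N.C2p,C,0.396983,-0.519442,-0.072046,nonlabeled,sugar_phosphate,
N.C3p,C,0.458181,-0.654136,-0.067999,nonlabeled,sugar_phosphate,
N.C4p,C,0.366874,-0.743634,0.006548,nonlabeled,sugar_phosphate,
N.O4p,O,0.249246,-0.664252,0.048574,nonlabeled,sugar_phosphate,
N.C5p,C,0.257697,-0.816473,-0.070125,nonlabeled,sugar_phosphate,
N.O5p,O,0.145781,-0.889718,-0.120712,nonlabeled,sugar_phosphate,
N.P,P,0.020040,-0.957387,-0.192893,nonlabeled,sugar_phosphate,
N.OP1,O,-0.078981,-1.057923,-0.148269,nonlabeled,sugar_phosphate,
N.OP2,O,0.159578,-0.936370,-0.148269,nonlabeled,sugar_phosphate,
N.O3p,O,0.464834,-0.727258,0.054712,nonlabeled,sugar_phosphate,
N.H1p,H,0.184623,-0.492453,-0.062037,nonlabeled,sugar_phosphate,
N.H2p,H,0.385324,-0.482736,-0.174015,nonlabeled,sugar_phosphate,
N.H2pp,H,0.463134,-0.443090,-0.031114,nonlabeled,sugar_phosphate,
N.H3p,H,0.480441,-0.692087,-0.167725,nonlabeled,sugar_phosphate,
N.H4p,H,0.338525,-0.831189,-0.051859,nonlabeled,sugar_phosphate,
N.H5p,H,0.181957,-0.888849,-0.040023,nonlabeled,sugar_phosphate,
N.H5pp,H,0.360769,-0.797740,-0.040023,nonlabeled,sugar_phosphate,
LT.N1,N,0.211884,0.389766,0.000000,labeled,base,Thymine
LT.C2,C,0.076093,0.382227,0.000000,labeled,base,Thymine
LT.N3,N,0.014727,0.260858,0.000000,labeled,base,Thymine
LT.C4,C,0.089152,0.147030,0.000000,labeled,base,Thymine
LT.C5,C,0.224943,0.154570,0.000000,labeled,base,Thymine
LT.C6,C,0.286309,0.275938,0.000000,labeled,base,Thymine
LT.O2,O,0.009330,0.484337,0.000000,labeled,base,Thymine
LT.O4,O,0.034104,0.038156,0.000000,labeled,base,Thymine
LT.H3,H,-0.086117,0.255259,0.000000,labeled,base,Thymine
LT.H6,H,0.395141,0.281980,0.000000,labeled,base,Thymine
LT.C7,C,0.307030,0.029023,0.000000,labeled,base,Thymine
LT.H71,H,0.240949,-0.057662,0.000000,labeled,base,Thymine
LT.H72,H,0.369942,0.026678,-0.088980,labeled,base,Thymine
LT.H73,H,0.369942,0.026678,0.088980,labeled,base,Thymine
NA.N9,N,0.211884,-0.389766,0.000000,nonlabeled,base,Adenine
NA.C8,C,0.274460,-0.267892,0.000000,nonlabeled,base,Adenine
NA.N7,N,0.177888,-0.170718,0.000000,nonlabeled,base,Adenine
NA.C5,C,0.055627,-0.232535,0.000000,nonlabeled,base,Adenine
NA.C4,C,0.076638,-0.367914,0.000000,nonlabeled,base,Adenine
NA.C6,C,-0.072120,-0.183042,0.000000,nonlabeled,base,Adenine
NA.N1,N,-0.178857,-0.268927,0.000000,nonlabeled,base,Adenine
NA.C2,C,-0.157846,-0.404306,0.000000,nonlabeled,base,Adenine
NA.N3,N,-0.030098,-0.453800,0.000000,nonlabeled,base,Adenine
NA.N6,N,-0.092825,-0.049639,0.000000,nonlabeled,base,Adenine
NA.H61,H,-0.151313,0.032703,0.000000,nonlabeled,base,Adenine
NA.H62,H,-0.062045,0.046557,0.000000,nonlabeled,base,Adenine
NA.H2,H,-0.242767,-0.472639,0.000000,nonlabeled,base,Adenine
NA.H8,H,0.382170,-0.251175,0.000000,nonlabeled,base,Adenine
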