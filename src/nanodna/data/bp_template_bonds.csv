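# covalent bonds of the template with idealized reference lengths
atom_i,atom_j,ref_nm
L.C1p,L.C2p,0.148000
L.C2p,L.C3p,0.148000
L.C3p,L.C4p,0.148000
L.C4p,L.O4p,0.148000
L.O4p,L.C1p,0.148000
L.C4p,L.C5p,0.152000
L.C5p,L.O5p,0.143000
L.O5p,L.P,0.160000
L.P,L.OP1,0.148000
L.P,L.OP2,0.148000
L.C3p,L.O3p,0.143000
L.C1p,L.H1p,0.109000
L.C2p,L.H2p,0.109000
L.C2p,L.H2pp,0.109000
L.C3p,L.H3p,0.109000
L.C4p,L.H4p,0.109000
L.C5p,L.H5p,0.109000
L.C5p,L.H5pp,0.109000
N.C1p,N.C2p,0.148000
N.C2p,N.C3p,0.148000
N.C3p,N.C4p,0.148000
N.C4p,N.O4p,0.148000
N.O4p,N.C1p,0.148000
N.C4p,N.C5p,0.152000
N.C5p,N.O5p,0.143000
N.O5p,N.P,0.160000
N.P,N.OP1,0.148000
N.P,N.OP2,0.148000
N.C3p,N.O3p,0.143000
N.C1p,N.H1p,0.109000
N.C2p,N.H2p,0.109000
N.C2p,N.H2pp,0.109000
N.C3p,N.H3p,0.109000
N.C4p,N.H4p,0.109000
N.C5p,N.H5p,0.109000
N.C5p,N.H5pp,0.109000
LT.N1,LT.C2,0.136000
LT.C2,LT.N3,0.136000
LT.N3,LT.C4,0.136000
LT.C4,LT.C5,0.136000
LT.C5,LT.C6,0.136000
LT.C6,LT.N1,0.136000
LT.N1,L.C1p,0.147000
LT.C2,LT.O2,0.122000
LT.C4,LT.O4,0.122000
LT.N3,LT.H3,0.101000
LT.C6,LT.H6,0.109000
LT.C5,LT.C7,0.150000
LT.C7,LT.H71,0.109000
LT.C7,LT.H72,0.109000
LT.C7,LT.H73,0.109000
NA.N9,NA.C8,0.137000
NA.C8,NA.N7,0.137000
NA.N7,NA.C5,0.137000
NA.C5,NA.C4,0.137000
NA.C4,NA.N9,0.137000
NA.N9,N.C1p,0.147000
NA.C5,NA.C6,0.137000
NA.C6,NA.N1,0.137000
NA.N1,NA.C2,0.137000
NA.C2,NA.N3,0.137000
NA.N3,NA.C4,0.137000
NA.C6,NA.N6,0.135000
NA.N6,NA.H61,0.101000
NA.N6,NA.H62,0.101000
NA.C2,NA.H2,0.109000
NA.C8,NA.H8,0.109000
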