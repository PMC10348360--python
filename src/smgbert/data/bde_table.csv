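elem_a,elem_b,order,bde_kj_mol,note
Br,C,single,285.0,literature-typical mean
C,C,aromatic,518.0,literature-typical mean
C,C,double,614.0,literature-typical mean
C,C,single,347.0,literature-typical mean
C,C,triple,839.0,literature-typical mean
C,Cl,single,327.0,literature-typical mean
C,F,single,485.0,literature-typical mean
C,I,single,213.0,literature-typical mean
C,N,aromatic,508.0,literature-typical mean
C,N,double,615.0,literature-typical mean
C,N,single,305.0,literature-typical mean
C,N,triple,891.0,literature-typical mean
C,O,double,745.0,literature-typical mean
C,O,single,358.0,literature-typical mean
C,P,single,264.0,literature-typical mean
C,S,double,573.0,literature-typical mean
C,S,single,259.0,literature-typical mean
Br,N,single,243.0,literature-typical mean
Cl,N,single,200.0,literature-typical mean
F,N,single,272.0,literature-typical mean
N,N,double,418.0,literature-typical mean
N,N,single,163.0,literature-typical mean
N,O,double,607.0,literature-typical mean
N,O,single,201.0,literature-typical mean
N,S,single,247.0,literature-typical mean
Br,O,single,235.0,literature-typical mean
Cl,O,single,203.0,literature-typical mean
F,O,single,190.0,literature-typical mean
O,O,single,146.0,literature-typical mean
O,P,double,544.0,literature-typical mean
O,P,single,335.0,literature-typical mean
O,S,double,522.0,literature-typical mean
O,S,single,265.0,literature-typical mean
Br,S,single,218.0,literature-typical mean
Cl,S,single,255.0,literature-typical mean
F,S,single,284.0,literature-typical mean
S,S,single,266.0,literature-typical mean
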