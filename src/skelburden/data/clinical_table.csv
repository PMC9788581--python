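patient_id,group,age,gleason,tnm,diagnosis,initial_psa,previous_treatments,bone_therapies,psa_at_pet
1,M,54,9 (5+4),T4N1M1,VII-2013,10,"RP, ADT, Rx",Ra,0.92
2,M,66,7 (4+3),T3aN1M0,VIII-08,7.7,"Rx, ADT, Ch, IT","Sm, D, A",87.5
3,M,78,6 (3+3),T2cN0M0,VII-11,15,"Rx, ADT, Ch","D, A, Ra",3.6
4,M,54,7 (4+3),T3N1M0,VI-09,21,"Rx, ADT, Ch","Z, D",4.9
5,M,61,7 (4+3),T2aN0MX,VII-11,,"RP, ADT, Ch","Z, Ra, A",1.39
6,M,60,7 (3+4),T3bN0M0,VI-10,13,"RP, ADT, Ch","Ra, A",0.35
7,M,68,7 (4+3),T3bN0M0,III-15,38,"RP, ADT, Ch","A, Ra",15
8,M,79,7 (3+4),T3N0M0,III-06,6.7,"RP, ADT, Rx, Ch","Z, Sm",0.98
9,M,77,9 (4+5),T4NXM1,II-04,490,"ADT, Rx, Ch",Z,4.39
10,M,66,8 (4+4),T4N1M1,VI-13,15,"ADT, Ch","A, Ra, D",447
11,M,57,7 (3+4),T2N1M1,I-13,968,"ADT, Rx, Ch","D, Sm",3.6
12,M,74,5,T1cN0M0,II-96,16,"RP, ADT, Rx, Ch","D, A",43.1
13,M,57,8 (4+4),T3aN0M0,III-14,58,"Rx, ADT",,2.6
14,M,76,8 (4+4),T2N0M0,VII-99,,"Rx, ADT, TURP, Ch",Z,293
I,N,77,8 (4+4),T3N0M0,VIII-16,0.3,,,8.29
II,N,65,7 (3+4),T3bN0M0,XI-16,17.1,Rx,,17.1
III,N,65,6 (3+3),T1cN0M0,II-16,6.3,Rx,,6.3
IV,N,83,9 (4+5),T3N1M1,XI-11,26.7,"ADT, Rx, Ch, IT",A,16.3
V,N,63,7 (4+3),T4N0M0,I-08,28,"RP, Rx, ADT",Z,1.98
VI,N,68,7 (4+3),T3N0M0,V-09,8,"RP, Rx, ADT","Z, Sm",1.7
VII,N,74,9 (5+4),T3N0M0,XII-13,0.48,"ADT, Rx",,<0.05
VIII,N,69,7 (4+3),T3N0M0,III-10,22,"Rx, ADT",Z,2.05
IX,N,77,7 (4+3),T1N0M0,X-16,8.3,"TURP, Rx",,2.23
X,N,50,7 (3+4),T1N0M0,XI-16,8.5,Rx,,8.5
XI,N,81,6 (3+3),T2bN0M0,XII-97,10.5,"RP, Rx, ADT",,7.94
XII,N,50,7 (3+4),T4N0M0,I-08,36,"RP, Rx",,7.81
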