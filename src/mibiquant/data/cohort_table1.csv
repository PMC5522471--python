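patient_id,sex,age_years,topography,nodule_size_mm,tirads,bethesda,visual_pattern,ri,woind_percent,histology
1,F,20,LL,34,4A,IV,3,108.4,-10,DTC
2,F,45,RL,35,4B,III,3,75.5,-23.6,BenignAdenoma
3,F,50,RL,16,4B,IV,3,144.4,-8,DTC
4,F,80,RL,45,4B,IV,3,194.3,-6.6,DTC
5,F,54,LL,33,4A,III,2,42.7,-40,ColloidGoitre
6,M,48,RL,27,3,IV,3,93.2,-26.6,BenignAdenoma
7,F,24,RL,22,4A,III,2,27.6,-45,ColloidGoitre
8,F,33,LL,28,3,III,3,89,-24.1,BenignAdenoma
9,F,66,LL,50,3,IV,2,-24.4,-34.9,BenignAdenoma
10,M,53,RL-I,25,4A,III,2,-3.7,-21.4,BenignAdenoma
11,F,33,RL,47,3,III,2,-15.5,-23.5,BenignAdenoma
12,F,48,LL,22,4A,III,2,45,-39,BenignAdenoma
13,F,62,RL,26,3,IV,2,5.55,-25.5,BenignAdenoma
14,F,78,LL,23,4A,III,2,-70,-28.5,BenignAdenoma
15,F,52,RL,35,4B,IV,2,6.61,-33,BenignAdenoma
16,F,46,LL,27,4B,III,2,-18.6,-28,BenignAdenoma
17,F,53,LL,22,4A,III,2,12.5,-35,BenignAdenoma
18,F,75,RL,30,4B,III,3,42.5,-30,BenignAdenoma
19,M,28,I,18,4A,IV,2,48,-17,DTC
20,F,61,RL,23,4B,IV,2,40.4,-26,BenignAdenoma
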