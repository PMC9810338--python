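name,mm_kda,n_cells_fcs,tau_d_us,tau_d_sem_us,alpha,alpha_sem,d_fcs_um2_s,d_fcs_sem_um2_s,n_cells_frap,d_frap_um2_s,d_frap_sem_um2_s
sfGFP,26.9,52,561,14,0.86,0.01,14.7,0.3,11,11.3,1.3
YggX,39.2,8,611,19,0.85,0.01,12.9,0.4,10,9.4,1.6
ClpS,39.2,11,1054,33,0.75,0.01,,,,,
FolK,45.1,8,734,24,0.87,0.01,11.6,0.4,,,
Crr,45.2,14,1065,36,0.87,0.01,,,,,
UbiC,45.7,14,1140,58,0.87,0.01,,,,,
CoaE,49.6,11,854,47,0.87,0.01,9.8,0.6,,,
Adk,50.6,23,802,26,0.88,0.00,10.6,0.4,16,9.8,1.5
Cmk,51.7,16,1163,58,0.87,0.01,,,,,
KdsB,54.6,11,1659,70,0.84,0.01,,,,,
Map,56.3,20,1830,78,0.81,0.01,,,,,
MmuM,60.4,14,2241,138,0.73,0.01,,,,,
PanE,60.8,18,1059,26,0.85,0.01,7.8,0.2,11,5.2,0.6
SolA,67.9,7,795,31,0.82,0.01,9.9,0.5,,,
Pgk,68.1,16,991,41,0.90,0.01,8.6,0.3,,,
EntC,69.9,15,1777,119,0.82,0.01,,,,,
AroA,73.1,9,995,69,0.86,0.01,8.7,0.7,,,
ThrC,74.1,14,908,28,0.87,0.01,9.1,0.3,,,
MurF,74.4,7,1008,76,0.85,0.02,8.3,0.7,,,
DsdA,74.9,14,1017,53,0.89,0.01,8.4,0.4,10,7.8,0.7
HemN,79.7,13,1262,54,0.86,0.01,6.7,0.4,,,
PrpD,80.9,12,1866,140,0.84,0.01,,,,,
DnaK,96.0,10,2296,78,0.76,0.01,,,,,
MalZ,96.0,9,3725,229,0.77,0.01,,,,,
GlcB,107.5,16,1315,45,0.86,0.01,6.4,0.2,10,6.7,1.1
MetE,111.7,8,1137,53,0.87,0.01,7.4,0.3,,,
LeuS,124.2,14,1637,75,0.86,0.01,5.1,0.2,,,
AcnA,124.7,19,1415,56,0.86,0.01,6.1,0.2,10,4.3,0.4
MetH,163.0,9,1402,45,0.81,0.01,5.8,0.1,15,4.0,0.5
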