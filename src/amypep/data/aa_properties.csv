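code,kd_hydropathy,hw_hydrophilicity,consensus_hydrophobicity,net_charge_ph7,isoelectric_point,sidechain_pka,polarity,polar_requirement,hb_donors,hb_acceptors,hb_capacity,residue_mass,vdw_volume,sidechain_heavy_atoms,bulkiness,rotatable_bonds,sidechain_length
class,HYDROPHOBIC,HYDROPHOBIC,HYDROPHOBIC,ELECTRICAL,ELECTRICAL,ELECTRICAL,ELECTRICAL,ELECTRICAL,HYDROGEN_BOND,HYDROGEN_BOND,HYDROGEN_BOND,STERIC,STERIC,STERIC,STERIC,STERIC,STERIC
A,1.8,-0.5,0.62,0.0,6.00,,8.1,7.0,0,0,0,71.08,88.6,1,11.50,0,1
R,-4.5,3.0,-2.53,1.0,10.76,12.48,10.5,9.1,5,0,5,156.19,173.4,7,14.28,4,6
N,-3.5,0.2,-0.78,0.0,5.41,,11.6,10.0,2,1,3,114.10,114.1,4,12.82,2,3
D,-3.5,3.0,-0.90,-1.0,2.77,3.65,13.0,13.0,0,2,2,115.09,111.1,4,11.68,2,3
C,2.5,-1.0,0.29,0.0,5.07,8.18,5.5,4.8,1,0,1,103.14,108.5,2,13.46,1,2
Q,-3.5,0.2,-0.85,0.0,5.65,,10.5,8.6,2,1,3,128.13,143.8,5,14.45,3,4
E,-3.5,3.0,-0.74,-1.0,3.22,4.25,12.3,12.5,0,2,2,129.12,138.4,5,13.57,3,4
G,-0.4,0.0,0.48,0.0,5.97,,9.0,7.9,0,0,0,57.05,60.1,0,3.40,0,0
H,-3.2,-0.5,-0.40,0.1,7.59,6.00,10.4,8.4,1,1,2,137.14,153.2,6,13.69,1,4
I,4.5,-1.8,1.38,0.0,6.02,,5.2,4.9,0,0,0,113.16,166.7,4,21.40,2,3
L,3.8,-1.8,1.06,0.0,5.98,,4.9,4.9,0,0,0,113.16,166.7,4,21.40,2,3
K,-3.9,3.0,-1.50,1.0,9.74,10.53,11.3,10.1,3,0,3,128.17,168.6,5,15.71,4,5
M,1.9,-1.3,0.64,0.0,5.74,,5.7,5.3,0,0,0,131.19,162.9,4,16.25,3,4
F,2.8,-2.5,1.19,0.0,5.48,,5.2,5.0,0,0,0,147.18,189.9,7,19.80,2,5
P,-1.6,0.0,0.12,0.0,6.30,,8.0,6.6,0,0,0,97.12,112.7,3,17.43,0,2
S,-0.8,0.3,-0.18,0.0,5.68,,9.2,7.5,1,1,2,87.08,89.0,2,9.47,1,2
T,-0.7,-0.4,-0.05,0.0,5.60,,8.6,6.6,1,1,2,101.10,116.1,3,15.77,1,2
W,-0.9,-3.4,0.81,0.0,5.89,,5.4,5.2,1,0,1,186.21,227.8,10,21.67,2,6
Y,-1.3,-2.3,0.26,0.0,5.66,10.07,6.2,5.4,1,1,2,163.18,193.6,8,18.03,2,6
V,4.2,-1.5,1.08,0.0,5.96,,5.9,5.6,0,0,0,99.13,140.0,3,21.57,1,2
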