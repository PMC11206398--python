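substituent,ic50_nM,dipole_gm_D,dipole_crystal_D,strain_crystal_kcal_mol,pop_gm_pct,pop_crystal_pct,rmsd_A,lambda_cal_nm,f_cal,lambda_crystal_nm,f_crystal,energy_gm_hartree
H,29,5.8286,5.8063,1.346,89.665,8.880,0.135,331.21,0.6391,333.17,0.6249,-933.798880
F,3.8,7.7915,5.9049,0.876,61.211,13.603,0.121,329.85,0.6462,330.98,0.6369,-1033.081728
Cl,0.31,8.0755,0.7406,8.193,63.493,0.001,0.657,329.88,0.6611,327.54,0.5294,-1393.425183
Br,0.025,8.2320,2.4071,8.279,62.711,0.001,0.692,329.99,0.6710,326.71,0.5295,-3507.379134
I,0.89,7.9890,5.8799,1.040,54.619,9.156,0.124,330.51,0.6853,331.84,0.6728,-1230.996026
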