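biochar,C_wt_pct,H_wt_pct,O_wt_pct,N_wt_pct,ash_wt_pct,H_C_ratio,O_C_ratio,BET_surface_area_m2_g,micropore_surface_area_m2_g,total_pore_volume_cm3_g,micropore_volume_cm3_g,pore_size_nm,conductivity_S_m,EDC_mmol_e_g,zeta_potential_mV
Char350,72.01,3.43,15.05,1.21,4.75,0.57,0.16,16.8,245,0.01,0.07,5.47,0.05,0.26,-35.3
Char500,77.21,2.59,12.35,1.17,5.80,0.40,0.12,261,331,0.28,0.10,4.34,0.04,1.22,-32.7
Char700,82.99,1.61,7.25,0.87,6.95,0.23,0.07,181,418,0.12,0.13,2.57,32.3,2.03,-14.3
Char900,80.16,1.09,7.80,1.01,9.50,0.16,0.07,449,543,0.29,0.19,2.58,154.4,1.51,-15.2
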