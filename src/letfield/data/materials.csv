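# Material constants for electron collision stopping powers.
# I_eV: mean excitation energy; Z_over_A per gram; Sternheimer density-effect
# coefficients (a, m, x0, x1, Cbar, delta0) on x = log10(beta*gamma).
# water_liquid: I = 75 eV (ICRU-37-era value; newer recommendations differ, see docs).
name,I_eV,density_g_cm3,Z_over_A,a,m,x0,x1,Cbar,delta0
water_liquid,75.0,1.0,0.55509,0.09116,3.4773,0.2400,2.8004,3.5017,0.0
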