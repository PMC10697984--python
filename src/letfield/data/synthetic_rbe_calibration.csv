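# SYNTHETIC calibration stand-in: maximum low-dose RBE for dicentric
# chromosome aberrations in human lymphocytes vs photon energy, relative to
# 60Co gamma rays. Constructed to follow a quadratic in log10(E) that passes
# ~1.0 at the 60Co energy and rises toward low photon energies, emulating the
# shape of published dicentric RBE_M data. Replace with measured data for any
# quantitative use.
photon_energy_MeV,rbe_m,std_u
0.01,3.960,0.45
0.02,3.163,0.45
0.04,2.567,0.45
0.08,2.114,0.45
0.15,1.692,0.35
0.3,1.363,0.35
0.662,1.156,0.35
1.25,0.960,0.28
2.5,0.887,0.28
5,1.115,0.28
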