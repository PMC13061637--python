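isotope,compartment,q_g,ea_ev,g_per100ev,a_g_mol,lambda_per_yr
238U,seawater,1.586e-5,51.7e6,0.65,238.0508,1.5513e-10
235U,seawater,1.15e-7,46.4e6,0.65,235.0439,9.8459e-10
232Th,seawater,2.4e-10,42.6e6,0.65,232.0381,4.9334e-11
40K,seawater,2.26e-4,1.31e6,0.22,39.9640,5.5543e-10
238U,nodule,2.48e-3,51.7e6,0.65,238.0508,1.5513e-10
235U,nodule,1.8e-5,46.4e6,0.65,235.0439,9.8459e-10
232Th,nodule,1.25e-2,42.6e6,0.65,232.0381,4.9334e-11
40K,nodule,4.1e-4,1.31e6,0.22,39.9640,5.5543e-10
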