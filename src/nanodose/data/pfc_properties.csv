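name,formula,M_g_mol,T_b_C,T_c_C,p_c_bar,rho_liquid_kg_m3,sigma_ref_N_m,sigma_ref_T_C,sigma_exponent,h_fg_tb_J_kg,watson_exponent
perfluorobutane,C4F10,238.03,-2.0,113.2,23.23,1594.0,0.0095,25.0,1.26,96300.0,0.38
perfluoropropane,C3F8,188.02,-36.7,71.9,26.80,1350.0,0.0130,-36.7,1.26,104300.0,0.38
perfluoropentane,C5F12,288.03,29.2,147.9,20.45,1620.0,0.0095,25.0,1.26,88200.0,0.38
perfluorohexane,C6F14,338.04,57.1,174.6,18.70,1680.0,0.0114,25.0,1.26,79000.0,0.38
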