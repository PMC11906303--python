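# Steady-state stoichiometric yields of the two N2O-respiring enrichments,
# together with the literature chemostat points at higher dilution rates
# used for the maintenance regression.
# units: d_h, d_sd [1/h]; n2o_ac_inf [mol/mol]; y_x_ac [C-mol/C-mol];
#        y_x_n2o [C-mol/mol]; y_n2o_ac [mol/mol]; y_nh4_x [mol/C-mol]
regime	source	d_h	d_sd	n2o_ac_inf	y_x_ac	y_x_ac_sd	y_x_n2o	y_x_n2o_sd	y_n2o_ac	y_n2o_ac_sd	y_nh4_x	y_nh4_x_sd
N2Oexc	this_study	0.006	0.001	12.8	0.15	0.03	0.09	0.02	3.42	0.35	0.41	0.15
N2Oexc	literature	0.028	0.001	15.9	0.25	0.02	0.16	0.01	3.06	0.2	0.28	0.02
N2Oexc	literature	0.089	0.003	26.1	0.27	0.01	0.17	0.01	3.1	0.17	0.28	0.01
N2Olim	this_study	0.006	0.001	1.8	0.24	0.04	0.15	0.03	3.1	0.15	0.44	0.13
N2Olim	literature	0.027	0.001	2.3	0.32	0.04	0.22	0.04	2.86	0.51	0.26	0.01
N2Olim	literature	0.086	0.003	2.7	0.33	0.03	0.26	0.02	2.49	0.29	0.25	0.02
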