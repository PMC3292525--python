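# Measured mass-isotopologue fractions and concentrations, isolated hepatocytes
# incubated 2 h with 20 mM glucose enriched 50% in [1,2-13C2]glucose.
# Values are natural-abundance corrected (means +/- sd over independent
# experiments). 22 quantitative rows for whole molecules + concentrations
# (glucose 4, lactate 5, glutamate fragments 3+3, glycogen 7), plus 6
# glycogen-fragment rows = 28 rows total.
experiment,metabolite,fragment,quantity,mean,sd,units
glucose_only,glucose,C1-C6,m0,0.512,0.0069,fraction
glucose_only,glucose,C1-C6,m1,0.00913,0.002,fraction
glucose_only,glucose,C1-C6,m2,0.478,0.00652,fraction
glucose_only,glucose,C1-C6,conc,19.7,1.92,mM
glucose_only,lactate,C1-C3,m0,0.86,0.0482,fraction
glucose_only,lactate,C1-C3,m1,0.0235,0.00802,fraction
glucose_only,lactate,C1-C3,m2,0.0946,0.0388,fraction
glucose_only,lactate,C1-C3,m3,0.022,0.0438,fraction
glucose_only,lactate,C1-C3,conc,0.81,0.51,mM
glucose_only,glutamate,C2-C5,m0,0.912,0.0343,fraction
glucose_only,glutamate,C2-C5,m1,0.0299,0.0116,fraction
glucose_only,glutamate,C2-C5,m2,0.0523,0.0217,fraction
glucose_only,glutamate,C2-C4,m0,0.919,0.0339,fraction
glucose_only,glutamate,C2-C4,m1,0.0365,0.00175,fraction
glucose_only,glutamate,C2-C4,m2,0.0446,0.0166,fraction
glucose_only,glycogen,C1-C6,m0,0.608,0.0388,fraction
glucose_only,glycogen,C1-C6,m1,0.0162,0.0033,fraction
glucose_only,glycogen,C1-C6,m2,0.362,0.0351,fraction
glucose_only,glycogen,C1-C6,m3,0.00399,0.0011,fraction
glucose_only,glycogen,C1-C6,m4,0.00961,0.0026,fraction
glucose_only,glycogen,C1-C6,m5,0.000464,0.00016,fraction
glucose_only,glycogen,C1-C6,conc,0.355,0.112,mg/mL
glucose_only,glycogen,C1-C4,m0,0.613,0.0448,fraction
glucose_only,glycogen,C1-C4,m1,0.0224,0.00834,fraction
glucose_only,glycogen,C1-C4,m2,0.357,0.0425,fraction
glucose_only,glycogen,C3-C6,m0,0.952,0.00767,fraction
glucose_only,glycogen,C3-C6,m1,0.00743,0.00211,fraction
glucose_only,glycogen,C3-C6,m2,0.0371,0.00467,fraction
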