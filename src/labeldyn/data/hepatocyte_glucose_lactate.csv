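# Measured mass-isotopologue fractions and concentrations, isolated hepatocytes
# incubated 2 h with 20 mM glucose + 9 mM lactate (+ 1 mM pyruvate).
# Experiment 1: glucose enriched 50% in [1,2-13C2]glucose.
# Experiment 2: lactate enriched 50% in [U-13C3]lactate.
# Rows printed as "--" in the source table are omitted.
experiment,metabolite,fragment,quantity,mean,sd,units
glucose_lactate_labelglc,glucose,C1-C6,m0,0.532,0.0098,fraction
glucose_lactate_labelglc,glucose,C1-C6,m1,0.00846,0.0022,fraction
glucose_lactate_labelglc,glucose,C1-C6,m2,0.459,0.0103,fraction
glucose_lactate_labelglc,glucose,C1-C6,conc,20.6,2.91,mM
glucose_lactate_labelglc,glycogen,C1-C6,m0,0.681,0.032,fraction
glucose_lactate_labelglc,glycogen,C1-C6,m1,0.0119,0.031,fraction
glucose_lactate_labelglc,glycogen,C1-C6,m2,0.302,0.031,fraction
glucose_lactate_labelglc,glycogen,C1-C6,m3,0.0017,0.001,fraction
glucose_lactate_labelglc,glycogen,C1-C6,m4,0.0032,0.0016,fraction
glucose_lactate_labelglc,glycogen,C1-C6,conc,0.263,0.084,mg/mL
glucose_lactate_labelglc,glycogen,C1-C4,m0,0.678,0.032,fraction
glucose_lactate_labelglc,glycogen,C1-C4,m1,0.016,0.0046,fraction
glucose_lactate_labelglc,glycogen,C1-C4,m2,0.3,0.032,fraction
glucose_lactate_labelglc,glycogen,C3-C6,m0,0.98,0.0101,fraction
glucose_lactate_labelglc,glycogen,C3-C6,m1,0.00408,0.0018,fraction
glucose_lactate_labelglc,glycogen,C3-C6,m2,0.0139,0.0078,fraction
glucose_lactate_labelglc,lactate,C1-C3,m0,0.974,0.026,fraction
glucose_lactate_labelglc,lactate,C1-C3,m1,0.0026,0.0019,fraction
glucose_lactate_labelglc,lactate,C1-C3,m2,0.0094,0.0037,fraction
glucose_lactate_labelglc,lactate,C1-C3,m3,0.00136,0.023,fraction
glucose_lactate_labelglc,lactate,C1-C3,conc,6.18,0.75,mM
glucose_lactate_labellac,glucose,C1-C6,m0,0.979,0.01,fraction
glucose_lactate_labellac,glucose,C1-C6,m1,0.0063,0.0055,fraction
glucose_lactate_labellac,glucose,C1-C6,m2,0.0055,0.0064,fraction
glucose_lactate_labellac,glucose,C1-C6,m3,0.0064,0.0016,fraction
glucose_lactate_labellac,glucose,C1-C6,conc,20.9,2.22,mM
glucose_lactate_labellac,glycogen,C1-C6,m0,0.909,0.026,fraction
glucose_lactate_labellac,glycogen,C1-C6,m1,0.017,0.0066,fraction
glucose_lactate_labellac,glycogen,C1-C6,m2,0.038,0.01,fraction
glucose_lactate_labellac,glycogen,C1-C6,m3,0.0273,0.0071,fraction
glucose_lactate_labellac,glycogen,C1-C6,m4,0.0036,0.0016,fraction
glucose_lactate_labellac,glycogen,C1-C6,m5,0.003,0.014,fraction
glucose_lactate_labellac,glycogen,C1-C6,conc,0.262,0.0691,mg/mL
glucose_lactate_labellac,glycogen,C1-C4,m0,0.93,0.024,fraction
glucose_lactate_labellac,glycogen,C1-C4,m1,0.033,0.009,fraction
glucose_lactate_labellac,glycogen,C1-C4,m2,0.019,0.0079,fraction
glucose_lactate_labellac,glycogen,C1-C4,m3,0.014,0.005,fraction
glucose_lactate_labellac,glycogen,C1-C4,m4,0.004,0.003,fraction
glucose_lactate_labellac,glycogen,C3-C6,m0,0.924,0.024,fraction
glucose_lactate_labellac,glycogen,C3-C6,m1,0.0265,0.007,fraction
glucose_lactate_labellac,glycogen,C3-C6,m2,0.027,0.0081,fraction
glucose_lactate_labellac,glycogen,C3-C6,m3,0.021,0.0067,fraction
glucose_lactate_labellac,lactate,C1-C3,m0,0.636,0.017,fraction
glucose_lactate_labellac,lactate,C1-C3,m1,0.0166,0.0025,fraction
glucose_lactate_labellac,lactate,C1-C3,m2,0.0318,0.0035,fraction
glucose_lactate_labellac,lactate,C1-C3,m3,0.316,0.0213,fraction
glucose_lactate_labellac,lactate,C1-C3,conc,3.18,0.43,mM
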