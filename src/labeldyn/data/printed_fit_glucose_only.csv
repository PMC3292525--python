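# Best-fit simulated values printed alongside the glucose-only measurements,
# for the channeling (two hexose-phosphate pools) and mixed (single pool)
# model variants.  Used to reproduce the published per-group chi-square
# arithmetic from printed numbers alone.
# Known correction: the glutamate C2-C4 m1 "mixed" entry is printed as 0.355
# in the source table, a misprint for 0.0355 (the measured value is 0.0365
# and the channeling value 0.0356); the corrected value is stored here.
experiment,metabolite,fragment,quantity,mean,sd,channeling,mixed
glucose_only,glucose,C1-C6,m0,0.512,0.0069,0.511,0.511
glucose_only,glucose,C1-C6,m1,0.00913,0.002,0.0084,0.00839
glucose_only,glucose,C1-C6,m2,0.478,0.00652,0.481,0.481
glucose_only,glucose,C1-C6,conc,19.7,1.92,20.4,20.2
glucose_only,lactate,C1-C3,m0,0.86,0.0482,0.839,0.81
glucose_only,lactate,C1-C3,m1,0.0235,0.00802,0.0237,0.0178
glucose_only,lactate,C1-C3,m2,0.0946,0.0388,0.133,0.17
glucose_only,lactate,C1-C3,m3,0.022,0.0438,0.00381,0.00145
glucose_only,lactate,C1-C3,conc,0.81,0.51,0.959,1.48
glucose_only,glutamate,C2-C5,m0,0.912,0.0343,0.912,0.912
glucose_only,glutamate,C2-C5,m1,0.0299,0.0116,0.0301,0.0298
glucose_only,glutamate,C2-C5,m2,0.0523,0.0217,0.0574,0.0567
glucose_only,glutamate,C2-C4,m0,0.919,0.0339,0.919,0.919
glucose_only,glutamate,C2-C4,m1,0.0365,0.00175,0.0356,0.0355
glucose_only,glutamate,C2-C4,m2,0.0446,0.0166,0.0454,0.0451
glucose_only,glycogen,C1-C6,m0,0.608,0.0388,0.598,0.658
glucose_only,glycogen,C1-C6,m1,0.0162,0.0033,0.0151,0.0271
glucose_only,glycogen,C1-C6,m2,0.362,0.0351,0.375,0.299
glucose_only,glycogen,C1-C6,m3,0.00399,0.0011,0.00422,0.00791
glucose_only,glycogen,C1-C6,m4,0.00961,0.0026,0.00748,0.00749
glucose_only,glycogen,C1-C6,m5,0.000464,0.00016,0.000432,0.000533
glucose_only,glycogen,C1-C6,conc,0.355,0.112,0.313,0.232
glucose_only,glycogen,C1-C4,m0,0.613,0.0448,0.627,0.679
glucose_only,glycogen,C1-C4,m1,0.0224,0.00834,0.0133,0.0297
glucose_only,glycogen,C1-C4,m2,0.357,0.0425,0.358,0.289
glucose_only,glycogen,C3-C6,m0,0.952,0.00767,0.952,0.951
glucose_only,glycogen,C3-C6,m1,0.00743,0.00211,0.0131,0.018
glucose_only,glycogen,C3-C6,m2,0.0371,0.00467,0.0333,0.0279
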