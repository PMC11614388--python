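name,parent_formula,derivatization,fragment_override_formula,n_tracer_carbons
lactate,C3H6O3,tbdms:2,,3
pyruvate,C3H4O3,tbdms:1,,3
succinate,C4H6O4,tbdms:2,,4
fumarate,C4H4O4,tbdms:2,,4
malate,C4H6O5,tbdms:3,,4
citrate,C6H8O7,tbdms:4,,6
aconitate,C6H6O6,tbdms:3,,6
alpha_ketoglutarate,C5H6O5,tbdms:2,,5
itaconate,C5H6O4,tbdms:2,,5
glutamate,C5H9NO4,tbdms:3,,5
glutamine,C5H10N2O3,tbdms:3,,5
glucose,C6H12O6,tbdms:5,,6
serine,C3H7NO3,tbdms:3,,3
acetylserine,C5H9NO4,tbdms:2,,5
glycine,C2H5NO2,tbdms:2,,2
acetylcarnitine,C9H17NO4,none,,9
palmitoylcarnitine,C23H45NO4,none,,23
palmitate,C16H32O2,tbdms:1,,16
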