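# FQFmu parameter set -- SYNTHETIC PLACEHOLDER VALUES (plausible magnitudes
# only; fitted values live in the original force-field publications).
# element  chi      eta      alpha    R_q      R_mu   (atomic units)
O          0.34000  0.58000  5.80000  1.20000  0.90000
H          0.17000  0.62500  2.60000  0.90000  0.70000
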