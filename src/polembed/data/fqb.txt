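# FQb parameter set -- SYNTHETIC PLACEHOLDER VALUES (plausible magnitudes only;
# fitted values live in the original force-field publications).
# element  chi      eta      alpha  R_q  R_mu   (atomic units)
O          0.36000  0.60000  -      -    -
H          0.15000  0.65000  -      -    -
C          0.30000  0.50000  -      -    -
N          0.45000  0.55000  -      -    -
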