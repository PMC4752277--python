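# Calibrated parameter set for phage lambda / E. coli MG1655 dynamics in
# monoxenic mouse gut (package default).
d = 0.25        # intestinal dilution rate, 1/h
r = 1.1         # maximal growth rate, 1/h
k = 4.6e9       # carrying capacity, cfu/g
x = 0.016       # induction rate, 1/h
l = 0.8         # latency rate, 1/h
y = 12.1        # burst size
a = 2.6e-9      # adsorption constant, g/h
g = 0.19        # lysogenization probability
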