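# Synthetic reconstruction of the worked example for the antitriangle
# centrality: two communities joined by the scored edge i-j.
# Community 1: diamond on {i, a, b, c} (4-clique minus the c-i edge).
# Community 2: 5-clique on {j, d, e, f, g}.
# The scored edge i-j has 24 potential P4s (left 12, central 8, right 4),
# 10 induced P4s (left 0, central 8, right 2), and centrality 10/25 = 2/5.
i j
i a
i b
a b
a c
b c
j d
j e
j f
j g
d e
d f
d g
e f
e g
f g
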