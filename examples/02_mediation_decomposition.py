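"""Two-step mediation arithmetic on published-style effect sizes.

Re-enters point estimates of the total effect c (lipid species -> DVT), the
exposure->mediator effect a, and the mediator->outcome effect b (inflammatory
protein -> DVT), and decomposes each triplet into indirect (a*b) and direct
(c - a*b) parts with the proportion mediated. Triplets whose indirect effect
opposes the total effect are flagged as masking.
"""

import mrmediate as mr

# (exposure, mediator, c, a, b) — effect sizes on the log-odds scale
TRIPLETS = [
    ("PC(17:0/20:4)", "SIRT2", 0.0015, -0.0435, 0.0024),
    ("PC(18:0/20:4)", "SIRT2", 0.0013, -0.0440, 0.0024),
    ("PC(14:0/18:2)", "CCL20", -0.0014, 0.0670, 0.0021),
    ("PC(15:0/18:2)", "CCL20", -0.0012, 0.0445, 0.0021),
    ("PC(18:0/20:5)", "CCL20", 0.0016, -0.054, 0.0021),
    ("TAG(58:7)", "CCL20", 0.0014, 0.0850, 0.0021),
]

results = [
    mr.two_step_decompose(c, a, b, exposure=e, mediator=m, outcome="DVT")
    for e, m, c, a, b in TRIPLETS
]
table = mr.mediated_proportion_table(results)
print(
    table[["exposure", "mediator", "indirect", "direct",
           "abs_proportion_pct", "classification"]]
    .to_string(index=False, float_format=lambda v: f"{v:.5g}")
)
print("\n|proportion| is 100*|a*b/c|: the share of the total lipid->DVT effect")
print("routed through the inflammatory protein. 'masking' rows transmit an")
print("indirect effect that opposes the total effect instead of explaining it.")
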