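"""Two-group design: does differential responding differ between groups?

With a two-level group column the package compares the groups' CS1 - CS2
difference scores with a pooled-variance independent-samples t-test and the
matching two-sample JZS Bayes factor (effective N = n1*n2/(n1+n2)).
"""

from condlab import SimConfig, analyze_table, render_report, simulate_conditioning

# group g1 conditions strongly (mu1 - mu2 = 1), group g2 weakly (0.2)
table = simulate_conditioning(
    SimConfig(n=30, mu1=1.0, mu2=0.0, groups=2, mu1_g2=0.2, mu2_g2=0.0, seed=21)
)
bundle = analyze_table(table, sensitivity=False)
print(render_report(bundle, interpret=True))

# The t statistic compares mean difference scores between groups; a large
# BF10 says the groups genuinely differ in how strongly they acquired the
# differential response.
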