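"""Prior-scale sensitivity: how the Bayes factor depends on the Cauchy scale.

Evaluates BF10 for the acquisition-phase summary statistics over a grid of
scales and reports whether the direction of the evidence is robust.
"""

from condlab import robustness_summary, sensitivity_curve

curve = sensitivity_curve(2.92, 40, grid=[0.3, 0.5, 0.707, 1.0, 1.414, 2.0])
for r, bf10, bf01 in curve.points:
    print(f"r = {r:5.3f}   BF10 = {bf10:6.2f}")
print()
print(robustness_summary(curve))

# Wider priors (larger r) put mass on large effects the data do not
# support, so BF10 shrinks as r grows -- but every scale here still favours
# H1, so the conclusion is robust to the prior choice.
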