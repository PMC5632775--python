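"""Full pipeline on a simulated data set: simulate, analyse, report.

Generates a 40-subject two-condition table with a moderate true paired
effect (delta ~ 0.5), runs the automatically selected t-test plus the JZS
Bayes factor with a prior-scale robustness analysis, and prints the
Markdown report the CLI would write.
"""

from condlab import JZSSpec, SimConfig, analyze_table, render_report, simulate_conditioning

table = simulate_conditioning(
    SimConfig(n=40, mu1=0.5, mu2=0.0, sigma=1.0, rho=0.5, seed=7)
)
bundle = analyze_table(table, spec=JZSSpec(r=0.707), sensitivity=True)
print(render_report(bundle, interpret=True, alpha=0.05))

# The report shows per-stimulus descriptives, the paired t-test line
# "t(39) = ..., p = ..., Cohen's d = ...", the Bayes factor at r = 0.707,
# and the robustness panel: whether the favoured hypothesis survives
# varying the prior scale from 0.1 to 2.0.
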