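"""Evidence categories, significance labels, the automatic results report,
and the two standard plots (condition means; BF10 vs prior scale).

Bayes factors are mapped onto the classical Jeffreys bands: 1-3 anecdotal
("not worth more than a bare mention"), 3-10 substantial, 10-30 strong,
30-100 very strong, >100 decisive, applied to whichever of BF10/BF01
exceeds 1.  Display rounding follows common reporting practice: t, d and
BF to 2 decimals, p to 3 decimals with a "p < .001" floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from condlab.data import ConditioningTable, ResultsBundle
from condlab.sensitivity import CANONICAL_SCALES, SensitivityCurve, robustness_summary

__all__ = [
    "EvidenceCategory",
    "categorize_bf",
    "significance_label",
    "render_report",
    "means_plot",
    "robustness_plot",
]

# Jeffreys band table: (upper bound, label, verbal descriptor)
_BANDS = (
    (3.0, "anecdotal", "not worth more than a bare mention"),
    (10.0, "substantial", "substantial evidence"),
    (30.0, "strong", "strong evidence"),
    (100.0, "very strong", "very strong evidence"),
    (float("inf"), "decisive", "decisive evidence"),
)


@dataclass(frozen=True)
class EvidenceCategory:
    """Jeffreys evidence category for a Bayes factor.

    ``direction`` is "H1", "H0" or "equal"; ``bf`` is the Bayes factor in
    the favoured direction (max(BF10, BF01)).
    """

    label: str
    direction: str
    bf: float
    description: str


def categorize_bf(bf10: float) -> EvidenceCategory:
    """Classify a BF10 into a Jeffreys evidence band.

    The band is applied to whichever of BF10/BF01 exceeds 1; BF = 1 maps to
    ``equal_support``.  Band edges are half-open as (1, 3], (3, 10], ... so
    a BF of exactly 3 is still anecdotal.
    """
    if not bf10 > 0:
        raise ValueError(f"Bayes factor must be positive, got {bf10}")
    if bf10 == 1.0:
        return EvidenceCategory("equal_support", "equal", 1.0, "equal support for both hypotheses")
    direction = "H1" if bf10 > 1.0 else "H0"
    bf = bf10 if bf10 > 1.0 else 1.0 / bf10
    for upper, label, desc in _BANDS:
        if bf <= upper:
            return EvidenceCategory(label, direction, bf, desc)
    raise AssertionError("unreachable")  # pragma: no cover


def significance_label(p: float, alpha: float = 0.05) -> str:
    """"significant" iff p < alpha (strict); boundary p == alpha is not."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return "significant" if p < alpha else "non-significant"


# ---------------------------------------------------------------------------
# number formatting (locale-independent, "." decimal separator)


def _fmt_p(p: float) -> str:
    if p < 0.001:
        return "p < .001"
    return f"p = {p:.3f}".replace("0.", ".", 1)


def _fmt2(x: float) -> str:
    return f"{x:.2f}"


def render_report(bundle: ResultsBundle, interpret: bool = False, alpha: float = 0.05) -> str:
    """Render the automatic Markdown results report.

    Sections: descriptives, frequentist, Bayesian, robustness (when a
    sensitivity curve is present) and, with ``interpret=True``, an
    interpretation block that labels the p-value against ``alpha`` and the
    Bayes factor by its Jeffreys category.  Output is deterministic: no
    timestamps, fixed number formatting.
    """
    f = bundle.freq
    b = bundle.bayes
    lines: list[str] = ["# Analysis report", "", "## Descriptive statistics", ""]
    lines.append("| group | stimulus | mean | sd | se | n |")
    lines.append("|---|---|---|---|---|---|")
    for _, row in bundle.descriptives.iterrows():
        lines.append(
            f"| {row['group']} | {row['stimulus']} | {row['mean']:.3f} | "
            f"{row['sd']:.3f} | {row['se']:.3f} | {int(row['n'])} |"
        )

    lines += ["", "## Frequentist results", ""]
    lines.append(f"Test: {f.test_name} samples t-test (selected automatically).")
    lines.append(
        f"t({f.nu}) = {_fmt2(f.t)}, {_fmt_p(f.p)}, Cohen's d = {_fmt2(f.cohen_d)}"
    )
    lines.append(
        f"Mean difference (CS1 - CS2): {f.mean_diff:.3f}, "
        f"95% CI [{f.ci95[0]:.3f}, {f.ci95[1]:.3f}]"
    )

    lines += ["", "## Bayesian results", ""]
    lines.append(
        f"Default Bayesian {f.test_name} samples t-test with a Cauchy prior "
        f"on the effect size, scale factor r = {b.r_used:g}."
    )
    lines.append(f"BF10 = {_fmt2(b.bf10)}, BF01 = {_fmt2(b.bf01)}")
    lines.append(
        f"Prior odds = {b.prior_odds:g}, posterior odds = {_fmt2(b.posterior_odds)}"
    )

    if bundle.sensitivity is not None:
        lines += ["", "## Robustness (sensitivity) analysis", ""]
        lines.append(robustness_summary(bundle.sensitivity))
        marks = []
        for r0 in CANONICAL_SCALES:
            idx = np.where(np.isclose(bundle.sensitivity.r, r0))[0]
            if idx.size:
                marks.append(f"r = {r0:g}: BF10 = {_fmt2(float(bundle.sensitivity.bf10[idx[0]]))}")
        if marks:
            lines.append("Canonical scales: " + "; ".join(marks) + ".")

    if interpret:
        lines += ["", "## Interpretation", ""]
        sig = significance_label(f.p, alpha)
        lines.append(
            f"The frequentist result is {sig} at alpha = {alpha:g} ({_fmt_p(f.p)})."
        )
        cat = categorize_bf(b.bf10)
        if cat.direction == "equal":
            lines.append("The Bayes factor gives equal support to both hypotheses.")
        else:
            which = (
                "the alternative hypothesis (a CR difference between the CSs)"
                if cat.direction == "H1"
                else "the null hypothesis (no CR difference between the CSs)"
            )
            lines.append(
                f"The Bayes factor ({_fmt2(cat.bf)} in favour of {cat.direction}) "
                f"falls in the '{cat.label}' band: {cat.description}, "
                f"for {which}."
            )
        lines.append(
            "This is a report based on the numerical values; researchers are "
            "free to question or ignore this interpretation."
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# plots


def _save_both(fig, path: str) -> list[str]:
    """Write the figure as both PNG and SVG next to ``path``."""
    import os

    base = os.path.splitext(path)[0]
    written = []
    for ext in (".png", ".svg"):
        fig.savefig(base + ext, dpi=150, bbox_inches="tight")
        written.append(base + ext)
    plt.close(fig)
    return written


def means_plot(table: ConditioningTable, path: str) -> list[str]:
    """Bar plot of per-stimulus (and per-group) means with +/-1 se bars."""
    from condlab.frequentist import descriptives

    desc = descriptives(table)
    groups = desc["group"].unique()
    fig, ax = plt.subplots(figsize=(5, 4))
    width = 0.35
    xs = np.arange(len(groups))
    for i, stim in enumerate(("cs1", "cs2")):
        sub = desc[desc["stimulus"] == stim].set_index("group").loc[groups]
        ax.bar(
            xs + (i - 0.5) * width,
            sub["mean"],
            width,
            yerr=sub["se"],
            capsize=4,
            label=stim.upper(),
        )
    ax.set_xticks(xs)
    ax.set_xticklabels([str(g) for g in groups])
    ax.set_ylabel("mean conditioned response")
    ax.set_xlabel("group")
    ax.legend(title="stimulus")
    ax.set_title("Condition means (+/- 1 SE)")
    return _save_both(fig, path)


def robustness_plot(curve: SensitivityCurve, path: str) -> list[str]:
    """BF10 (log y-axis) against the Cauchy scale r, with a reference line
    at BF = 1 and markers at the canonical scales."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.r, curve.bf10, "-", color="C0", lw=1.5)
    ax.axhline(1.0, color="grey", ls="--", lw=1, label="BF10 = 1")
    for r0 in CANONICAL_SCALES:
        idx = np.where(np.isclose(curve.r, r0))[0]
        if idx.size:
            ax.plot(r0, curve.bf10[idx[0]], "o", color="C3", ms=6)
            ax.annotate(
                f"r={r0:g}",
                (r0, curve.bf10[idx[0]]),
                textcoords="offset points",
                xytext=(4, 4),
                fontsize=8,
            )
    ax.set_yscale("log")
    ax.set_xlabel("Cauchy prior scale r")
    ax.set_ylabel("BF10")
    ax.set_title("Bayes factor robustness")
    ax.legend()
    return _save_both(fig, path)
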