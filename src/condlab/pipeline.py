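"""High-level analysis entry points tying the modules together."""

from __future__ import annotations

from typing import Optional, Sequence

from condlab.bayes import JZSSpec, bf_from_t
from condlab.data import ConditioningTable, ResultsBundle
from condlab.frequentist import cohen_d_from_t, descriptives, run_frequentist, FreqResult
from condlab.sensitivity import sensitivity_curve

__all__ = ["analyze_table", "analyze_summary"]


def analyze_table(
    table: ConditioningTable,
    spec: JZSSpec = JZSSpec(),
    sensitivity: bool = False,
    scales: Optional[Sequence[float]] = None,
    alpha: float = 0.05,
) -> ResultsBundle:
    """Full analysis of a conditioning table: descriptives, the
    automatically selected t-test, the JZS Bayes factor and (optionally)
    the prior-scale sensitivity curve."""
    freq = run_frequentist(table)
    if freq.test_name == "paired":
        n1, n2 = freq.n, None
    else:
        n1, n2 = freq.n
    bayes = bf_from_t(freq.t, n1, n2, spec=spec)
    bayes.design = freq.test_name
    curve = None
    if sensitivity or scales is not None:
        curve = sensitivity_curve(freq.t, n1, n2, grid=scales, prior_odds=spec.prior_odds)
    return ResultsBundle(
        descriptives=descriptives(table), freq=freq, bayes=bayes,
        sensitivity=curve, alpha=alpha,
    )


def analyze_summary(
    t: float,
    n1: int,
    n2: Optional[int] = None,
    design: Optional[str] = None,
    spec: JZSSpec = JZSSpec(),
    sensitivity: bool = False,
    scales: Optional[Sequence[float]] = None,
) -> dict:
    """Analysis from summary statistics (t, sample sizes) only.

    ``design`` defaults to "paired" when ``n2`` is absent and
    "independent" when it is given.  Returns a dict with the frequentist
    quantities recoverable from the summary (t, nu, p, Cohen's d), the
    :class:`~condlab.bayes.BayesResult`, and the sensitivity curve if
    requested.
    """
    from scipy import stats

    if design is None:
        design = "independent" if n2 is not None else "paired"
    if design == "paired" and n2 is not None:
        raise ValueError("paired design takes a single sample size")
    if design == "independent" and n2 is None:
        raise ValueError("independent design needs n2")
    nu = n1 - 1 if n2 is None else n1 + n2 - 2
    p = 2.0 * stats.t.sf(abs(t), nu)
    bayes = bf_from_t(t, n1, n2, spec=spec)
    bayes.design = design
    out = {
        "design": design,
        "t": float(t),
        "nu": nu,
        "p": float(p),
        "cohen_d": float(cohen_d_from_t(t, n1, n2)),
        "bayes": bayes,
    }
    if sensitivity or scales is not None:
        out["sensitivity"] = sensitivity_curve(t, n1, n2, grid=scales, prior_odds=spec.prior_odds)
    return out
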