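"""Default (Jeffreys--Zellner--Siow) Bayesian t-test Bayes factors.

The null hypothesis fixes the population standardised effect size at
delta = 0; the alternative places a Cauchy(0, r) prior on delta.  The Bayes
factor BF10 is the ratio of the marginal likelihood of the observed t
statistic under the two hypotheses:

    BF10 = [ integral f_nu(t; delta*sqrt(N)) Cauchy(delta; 0, r) d delta ]
           / f_nu(t; 0)

where ``f_nu(.; ncp)`` is the noncentral Student-t density with ``nu``
degrees of freedom and ``N`` the effective sample size (n for the paired
design, n1*n2/(n1+n2) for the two-sample design).

Two independent formulations are computed on every call:

* the primary 1-D integral over delta, compactified by delta = r*tan(theta)
  so the Cauchy prior becomes the uniform measure d theta / pi on
  (-pi/2, pi/2);
* the scale-mixture form, integrating the normal-on-delta marginal over the
  inverse-gamma(1/2, r^2/2) mixing density of the Cauchy.

They must agree to 1e-6 relative; disagreement raises rather than returning
a silently wrong number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import integrate, special, stats

from condlab.data import ConditioningTable

__all__ = ["JZSSpec", "BayesResult", "bf_from_t", "bf_from_data", "posterior_odds"]

#: default Cauchy prior scale on the standardised effect size
DEFAULT_SCALE = 0.707

_CROSSCHECK_RTOL = 1e-6


@dataclass(frozen=True)
class JZSSpec:
    """Prior specification for the default Bayesian t-test.

    ``r`` is the Cauchy scale on the standardised effect size delta
    (default 0.707, the common software default); ``prior_odds`` the
    P(H1)/P(H0) odds before seeing data (default 1, equal odds).
    """

    r: float = DEFAULT_SCALE
    prior_odds: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r > 0 and math.isfinite(self.r)):
            raise ValueError(f"Cauchy scale r must be a positive finite number, got {self.r}")
        if not (self.prior_odds > 0 and math.isfinite(self.prior_odds)):
            raise ValueError(f"prior_odds must be positive and finite, got {self.prior_odds}")


@dataclass
class BayesResult:
    """JZS Bayes factor with the quantities that contextualise it."""

    bf10: float
    bf01: float
    r_used: float
    effective_n: float
    nu: int
    prior_odds: float
    posterior_odds: float
    quad_error: float
    design: Optional[str] = None


def _delta_integral_bf(t: float, nu: int, N: float, r: float) -> tuple[float, float]:
    """Primary formulation: marginalise the noncentral-t density over the
    Cauchy prior via the substitution delta = r*tan(theta).

    Returns (bf10, relative quadrature error bound).
    """

    sqrtN = math.sqrt(N)

    def lik(delta: float) -> float:
        # scipy's noncentral-t density yields NaN or raises at astronomically
        # large noncentrality, where the true density has underflowed to zero
        try:
            val = stats.nct.pdf(t, nu, delta * sqrtN)
        except OverflowError:
            return 0.0
        return val if math.isfinite(val) else 0.0

    def theta_integrand(theta: float) -> float:
        # substitution delta = r*tan(theta): Cauchy measure becomes d theta/pi
        return lik(r * math.tan(theta)) / math.pi

    def delta_integrand(delta: float) -> float:
        return lik(delta) * stats.cauchy.pdf(delta, 0.0, r)

    # two features need resolving: the Cauchy core of width r at delta = 0
    # (handled exactly by the tan substitution) and the likelihood peak of
    # width ~1/sqrt(N) at the MLE delta_hat = t/sqrt(N).  When r is tiny the
    # peak sits in the far prior tail, squeezed against theta = pi/2, so the
    # outer region is integrated in delta space instead.
    delta_hat = t / sqrtN
    A = abs(delta_hat) + 15.0 * (1.0 + abs(t)) / sqrtN + 10.0 * r
    c = 10.0 * r
    if c >= A:
        theta_peak = math.atan(delta_hat / r)
        num, err = integrate.quad(
            theta_integrand, -math.pi / 2, math.pi / 2,
            epsabs=0.0, epsrel=1e-10, limit=400, points=[theta_peak, 0.0],
        )
    else:
        theta_c = math.atan(c / r)
        num, err = integrate.quad(
            theta_integrand, -theta_c, theta_c,
            epsabs=0.0, epsrel=1e-10, limit=400, points=[0.0],
        )
        # outer pieces in x = log|delta| space, where the 1/delta^2 Cauchy
        # tail becomes a smooth exponential and the likelihood bump is wide
        lo, hi = math.log(c), math.log(A)
        for sign in (1.0, -1.0):

            def log_integrand(x: float, s=sign) -> float:
                d = s * math.exp(x)
                return delta_integrand(d) * abs(d)

            pts = None
            if sign * delta_hat > 0 and c < abs(delta_hat) < A:
                pts = [math.log(abs(delta_hat))]
            v, e = integrate.quad(
                log_integrand, lo, hi,
                epsabs=1e-18, epsrel=1e-10, limit=400, points=pts,
            )
            num += v
            err += e
    if num <= 0 or not math.isfinite(num):
        raise RuntimeError("quadrature failed: non-positive marginal likelihood")
    rel_err = err / num
    if rel_err > 1e-8:
        raise RuntimeError(f"quadrature did not converge: relative error {rel_err:.2e}")
    den = stats.t.pdf(t, nu)
    return num / den, rel_err


def _g_mixture_bf(t: float, nu: int, N: float, r: float) -> float:
    """Cross-check formulation: the Cauchy prior as a normal scale mixture.

    delta | g ~ N(0, g) with g ~ inverse-gamma(1/2, r^2/2).  Conditional on
    g, the marginal density of t is a scaled central-t kernel, so BF10
    reduces to a 1-D integral over g (the central-t constants cancel):

        BF10 = int_0^inf (1+Ng)^{-1/2} [1 + t^2/((1+Ng) nu)]^{-(nu+1)/2}
                         pi_ig(g) dg  /  (1 + t^2/nu)^{-(nu+1)/2}

    Integrated in the rescaled variable u = g/r^2, under which the mixing
    density is inverse-gamma(1/2, 1/2) independent of r, so the integrand's
    mass stays near u ~ 1 even for extreme scales.
    """
    t2 = t * t
    log_den = -(nu + 1) / 2.0 * math.log1p(t2 / nu)
    log_c = -0.5 * math.log(2.0) - math.lgamma(0.5)  # inverse-gamma(1/2, 1/2) constant

    def integrand(u: float) -> float:
        if u <= 0.0:
            return 0.0
        m = 1.0 + N * r * r * u
        log_lik = -0.5 * math.log(m) - (nu + 1) / 2.0 * math.log1p(t2 / (m * nu))
        log_prior = log_c - 1.5 * math.log(u) - 0.5 / u
        return math.exp(log_lik + log_prior - log_den)

    # the integrand can be bimodal -- the prior concentrates at u ~ 1 while
    # the likelihood peaks near u = t^2/(N r^2), arbitrarily far away for
    # small r -- so integrate in y = log(u), where both bumps are O(1) wide
    def log_integrand(y: float) -> float:
        u = math.exp(y)
        return integrand(u) * u

    u_lik = t * t / (N * r * r) if t != 0.0 else 1.0
    y_lik = math.log(u_lik)
    y_lo, y_hi = -50.0, max(50.0, y_lik + 50.0)
    pts = sorted({0.0, min(max(y_lik, y_lo), y_hi)})
    val, err = integrate.quad(
        log_integrand, y_lo, y_hi, epsabs=0.0, epsrel=1e-10, limit=800, points=pts
    )
    if val <= 0 or not math.isfinite(val):
        raise RuntimeError("g-mixture quadrature failed")
    return val


def bf_from_t(
    t: float,
    n1: int,
    n2: Optional[int] = None,
    spec: JZSSpec = JZSSpec(),
) -> BayesResult:
    """JZS Bayes factor from summary statistics.

    Parameters
    ----------
    t
        Observed t statistic.
    n1, n2
        Sample size(s): ``n2=None`` for the paired/one-sample design
        (nu = n1-1, N = n1); otherwise the pooled-variance two-sample
        design (nu = n1+n2-2, N = n1*n2/(n1+n2)).
    spec
        Cauchy scale and prior odds.

    Both the delta-integral and the g-mixture formulation are evaluated;
    a relative disagreement beyond 1e-6 raises ``RuntimeError``.
    """
    if not math.isfinite(t):
        raise ValueError(f"t must be finite, got {t}")
    if n1 < 2 or (n2 is not None and n2 < 2):
        raise ValueError("each sample must contain at least 2 observations")
    if n2 is None:
        nu, N = n1 - 1, float(n1)
    else:
        nu, N = n1 + n2 - 2, n1 * n2 / (n1 + n2)

    bf10, rel_err = _delta_integral_bf(t, nu, N, spec.r)
    bf_check = _g_mixture_bf(t, nu, N, spec.r)
    if abs(bf10 - bf_check) > _CROSSCHECK_RTOL * abs(bf_check):
        raise RuntimeError(
            f"Bayes factor formulations disagree: {bf10!r} (delta-integral) "
            f"vs {bf_check!r} (g-mixture)"
        )
    return BayesResult(
        bf10=bf10,
        bf01=1.0 / bf10,
        r_used=spec.r,
        effective_n=N,
        nu=nu,
        prior_odds=spec.prior_odds,
        posterior_odds=spec.prior_odds * bf10,
        quad_error=rel_err,
    )


def bf_from_data(table: ConditioningTable, spec: JZSSpec = JZSSpec()) -> BayesResult:
    """JZS Bayes factor from raw data, with automatic design selection.

    Computes the design's t statistic through the frequentist module and
    delegates to :func:`bf_from_t`; the result records which design was
    selected.
    """
    from condlab.frequentist import run_frequentist

    freq = run_frequentist(table)
    if freq.test_name == "paired":
        res = bf_from_t(freq.t, freq.n, spec=spec)
    else:
        n1, n2 = freq.n
        res = bf_from_t(freq.t, n1, n2, spec=spec)
    res.design = freq.test_name
    return res


def posterior_odds(spec: JZSSpec, bf10: float) -> float:
    """Posterior odds P(H1|data)/P(H0|data) = prior_odds * BF10."""
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    return spec.prior_odds * bf10
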