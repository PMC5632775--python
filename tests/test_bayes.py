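import numpy as np
import pytest
from scipy import stats

from condlab import (
    ConditioningTable,
    JZSSpec,
    SimConfig,
    bf_from_data,
    bf_from_t,
    null_batch,
    posterior_odds,
    simulate_conditioning,
)
from condlab.bayes import _delta_integral_bf, _g_mixture_bf


def brute_force_bf10(t, nu, N, r, n_grid=400_001, width=60.0):
    """Dense-trapezoid oracle for the delta-marginal Bayes factor."""
    delta = np.linspace(-width * r, width * r, n_grid)
    integrand = stats.nct.pdf(t, nu, delta * np.sqrt(N)) * stats.cauchy.pdf(delta, 0, r)
    num = np.trapezoid(integrand, delta)
    return num / stats.t.pdf(t, nu)


class TestBfFromT:
    def test_null_t_brute_force_oracle(self):
        res = bf_from_t(0.0, 20, spec=JZSSpec(r=0.707))
        assert res.bf10 < 1
        oracle = brute_force_bf10(0.0, 19, 20, 0.707)
        assert res.bf10 == pytest.approx(oracle, rel=1e-5)

    @pytest.mark.parametrize("t, n", [(1.7, 12), (-2.4, 35), (3.1, 8)])
    def test_brute_force_oracle_various(self, t, n):
        res = bf_from_t(t, n)
        oracle = brute_force_bf10(t, n - 1, n, 0.707)
        assert res.bf10 == pytest.approx(oracle, rel=1e-5)

    def test_tiny_scale_limit(self):
        # as r -> 0 the alternative collapses onto the null, so BF10 -> 1
        res = bf_from_t(2.92, 40, spec=JZSSpec(r=1e-6))
        assert res.bf10 == pytest.approx(1.0, abs=1e-4)

    def test_reciprocity_exact(self):
        res = bf_from_t(2.0, 25)
        assert res.bf10 * res.bf01 == pytest.approx(1.0, rel=1e-15)

    def test_symmetry_in_t(self):
        a, b = bf_from_t(2.3, 18), bf_from_t(-2.3, 18)
        assert a.bf10 == pytest.approx(b.bf10, rel=1e-9)

    def test_monotone_in_abs_t(self):
        bfs = [bf_from_t(t, 30).bf10 for t in (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)]
        assert np.all(np.diff(bfs) > 0)

    def test_two_sample_effective_n(self):
        res = bf_from_t(2.0, 10, 30)
        assert res.effective_n == pytest.approx(10 * 30 / 40)
        assert res.nu == 38

    def test_metadata_and_quad_error(self):
        res = bf_from_t(2.92, 40, spec=JZSSpec(r=0.707, prior_odds=2.0))
        assert res.r_used == 0.707
        assert res.posterior_odds == pytest.approx(2.0 * res.bf10)
        assert res.quad_error < 1e-6

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bf_from_t(np.inf, 20)
        with pytest.raises(ValueError):
            bf_from_t(1.0, 1)
        with pytest.raises(ValueError):
            JZSSpec(r=-1.0)
        with pytest.raises(ValueError):
            JZSSpec(prior_odds=0.0)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        for t, n in [(2.92, 40), (2.185, 40), (0.0, 20), (-1.5, 12)]:
            mine = bf_from_t(t, n).bf10
            ref = float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707))
            assert mine == pytest.approx(ref, rel=1e-6)
        mine2 = bf_from_t(2.0, 15, 20).bf10
        ref2 = float(pg.bayesfactor_ttest(2.0, 15, 20, paired=False, r=0.707))
        assert mine2 == pytest.approx(ref2, rel=1e-6)


class TestFormulationEquivalence:
    @pytest.mark.parametrize("n", [5, 20, 40, 200])
    @pytest.mark.parametrize("r", [0.5, 0.707, 1.0, 1.414])
    def test_delta_integral_vs_g_mixture(self, n, r):
        for t in np.arange(-5.0, 5.01, 1.0):
            bf_delta, _ = _delta_integral_bf(float(t), n - 1, float(n), r)
            bf_g = _g_mixture_bf(float(t), n - 1, float(n), r)
            assert bf_delta == pytest.approx(bf_g, rel=1e-6)


class TestBfFromData:
    def test_degenerate_variance_error(self):
        t = ConditioningTable(cs1=[1.0, 2, 4], cs2=[0.0, 1, 3])  # constant shift
        with pytest.raises(ValueError, match="zero-variance"):
            bf_from_data(t)

    def test_large_effect_overwhelming_evidence(self):
        # delta = 0.8 at n = 500 must yield decisive evidence for H1
        cfg = SimConfig(n=500, mu1=0.8, mu2=0.0, sigma=1.0, rho=0.5, seed=5)
        table = simulate_conditioning(cfg)
        res = bf_from_data(table)
        assert res.design == "paired"
        assert res.bf10 > 100

    def test_null_data_supports_h0(self):
        # at n = 500 under the null, BF01 > 3 in the majority of replicates
        cfg = SimConfig(n=500, mu1=0.0, mu2=0.0, sigma=1.0, rho=0.5, seed=99)
        tables = null_batch(cfg, reps=200)
        bf01 = np.array([bf_from_data(tb).bf01 for tb in tables])
        assert np.median(bf01) > 3

    def test_sample_size_consistency(self):
        # median BF10 at fixed delta != 0 is nondecreasing in n
        medians = []
        for n in (20, 80, 320):
            bfs = []
            for i in range(30):
                cfg = SimConfig(n=n, mu1=0.4, mu2=0.0, sigma=1.0, rho=0.5, seed=1000 + i)
                bfs.append(bf_from_data(simulate_conditioning(cfg)).bf10)
            medians.append(np.median(bfs))
        assert medians[0] <= medians[1] <= medians[2]

    def test_grouped_design_delegates_to_two_sample(self, grouped_table):
        res = bf_from_data(grouped_table)
        assert res.design == "independent"
        assert res.nu == grouped_table.n - 2


class TestPosteriorOdds:
    @pytest.mark.parametrize(
        "prior_odds, bf10, expected", [(1.0, 6.57, 6.57), (2.0, 0.5, 1.0), (1.0, 1.0, 1.0)]
    )
    def test_examples(self, prior_odds, bf10, expected):
        assert posterior_odds(JZSSpec(prior_odds=prior_odds), bf10) == pytest.approx(expected)

    def test_rejects_nonpositive_bf(self):
        with pytest.raises(ValueError):
            posterior_odds(JZSSpec(), 0.0)
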