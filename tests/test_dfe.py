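"""PRF machinery and DFE fitting against independent quadrature oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import binom

from gcbias.codon import ALL
from gcbias.dfe import (
    DFEModel,
    alpha_omega,
    expected_sfs,
    expected_sfs_entry,
    fit,
    fixation_factor,
    profile_ci,
    sojourn_density,
)
from gcbias.polymorphism import SFSPair
from gcbias.simulate import simulate_divergence_counts, simulate_sfs_counts


def oracle_entry(S, i, n):
    """Brute-force adaptive quadrature of the PRF integral."""

    def H(x):
        if S == 0:
            return 1.0 / x
        return (1 - math.exp(-S * (1 - x))) / ((1 - math.exp(-S)) * x * (1 - x))

    val, _ = quad(lambda x: H(x) * binom.pmf(i, n, x), 0, 1, limit=400)
    return val


class TestExpectedSfs:
    def test_neutral_is_one_over_i(self):
        n = 15
        np.testing.assert_allclose(
            expected_sfs(0.0, n), 1.0 / np.arange(1, n), rtol=1e-10
        )

    @pytest.mark.parametrize("S", [-50.0, -5.0, -1.0, 1.0, 5.0, 50.0])
    def test_matches_quadrature_oracle(self, S):
        n = 10
        for i in (1, 3, 9):
            assert expected_sfs_entry(S, i, n) == pytest.approx(
                oracle_entry(S, i, n), rel=1e-8
            )

    def test_fixed_example(self):
        assert expected_sfs_entry(1.0, 3, 10) == pytest.approx(
            oracle_entry(1.0, 3, 10), rel=1e-8
        )

    def test_strong_negative_concentrates_on_singletons(self):
        e = expected_sfs(-200.0, 10)
        ratios = e[1:] / e[:-1]
        neutral_ratios = (1.0 / np.arange(2, 10)) / (1.0 / np.arange(1, 9))
        assert np.all(ratios < neutral_ratios)

    def test_extreme_s_is_finite(self):
        for S in (-1e7, -1e4, 1e4):
            assert np.all(np.isfinite(expected_sfs(S, 20)))

    def test_invalid_i(self):
        with pytest.raises(ValueError):
            expected_sfs_entry(1.0, 0, 10)


class TestFixationFactor:
    def test_neutral_limit(self):
        assert fixation_factor(0.0) == pytest.approx(1.0)
        assert fixation_factor(1e-12) == pytest.approx(1.0)

    def test_known_values(self):
        assert fixation_factor(2.0) == pytest.approx(2 / (1 - math.exp(-2)))
        assert fixation_factor(-2.0) == pytest.approx(-2 / (1 - math.exp(2)))

    def test_no_overflow(self):
        assert fixation_factor(-5000.0) == pytest.approx(0.0, abs=1e-300)
        assert fixation_factor(5000.0) == pytest.approx(5000.0)


def _pair(rng, model=None, L_s=3e5, L_n=8e5, theta=0.005, n=20, B=0.0,
          p_adapt=0.0, s_adv=25.0, distortion=None, D=None):
    syn, nonsyn = simulate_sfs_counts(
        rng, None, L_s, L_n, theta, n, B=B, dfe=model,
        p_adapt=p_adapt, s_adv=s_adv, distortion=distortion,
    )
    Ds, Dn = D if D else (0.0, 0.0)
    return SFSPair(ALL, n, syn, nonsyn, L_s, L_n, D_syn=Ds, D_nonsyn=Dn)


class TestFit:
    def test_neutral_self_consistency(self, rng):
        pair = _pair(rng, model=None)
        f = fit(pair, "GammaZero", seed=0)
        # predicted dN/dS under the fitted DFE is ~1 for neutral data
        assert f.model.omega_na() == pytest.approx(1.0, abs=0.05)

    def test_shape_recovery(self, rng):
        truth = DFEModel("GammaZero", shape=0.4, s_mean=2000)
        hits = 0
        for rep in range(6):
            f = fit(_pair(rng, truth), "GammaZero", seed=rep, with_alpha=False)
            hits += abs(f.model.shape - 0.4) <= 0.1
        assert hits >= 5

    def test_saturation_of_nuisance_classes(self, rng):
        """With r_i free, fitted per-class totals match observation exactly."""
        truth = DFEModel("GammaZero", shape=0.4, s_mean=500)
        pair = _pair(rng, truth)
        f = fit(pair, "GammaZero", seed=0, with_alpha=False)
        i = np.arange(1, pair.n)
        e = f.model.nonsyn_expected_sfs(pair.n)
        a = f.r * f.theta
        predicted = a * (pair.L_syn / i) + a * pair.L_nonsyn * e
        np.testing.assert_allclose(
            predicted, pair.syn_sfs + pair.nonsyn_sfs, rtol=1e-9
        )

    def test_distortion_invariance(self, rng):
        """Multiplying both spectra by known c_i leaves the DFE estimate
        unchanged and is absorbed by r_i (up to the r_1=1 normalisation)."""
        truth = DFEModel("GammaZero", shape=0.4, s_mean=800)
        pair = _pair(rng, truth)
        c = np.linspace(1.0, 2.5, pair.n - 1)
        distorted = SFSPair(
            ALL, pair.n, pair.syn_sfs * c, pair.nonsyn_sfs * c,
            pair.L_syn, pair.L_nonsyn,
        )
        f0 = fit(pair, "GammaZero", seed=0, with_alpha=False)
        f1 = fit(distorted, "GammaZero", seed=0, with_alpha=False)
        # finite-sample: the c_i reweight likelihood classes, so the argmax
        # moves slightly; estimates agree within a few percent
        assert f1.model.shape == pytest.approx(f0.model.shape, rel=0.05)
        assert f1.model.s_mean == pytest.approx(f0.model.s_mean, rel=0.20)
        recovered = f1.r / f0.r
        np.testing.assert_allclose(recovered / recovered[0], c / c[0], rtol=0.02)

    def test_gamma_expo_nests_gamma_zero(self, rng):
        truth = DFEModel("GammaZero", shape=0.4, s_mean=500)
        pair = _pair(rng, truth)
        f0 = fit(pair, "GammaZero", seed=0, with_alpha=False)
        f1 = fit(pair, "GammaExpo", seed=0, with_alpha=False)
        assert f1.loglik >= f0.loglik - 1e-6


class TestAlphaOmega:
    def test_identity(self, rng):
        truth = DFEModel("GammaZero", shape=0.4, s_mean=1000)
        pair = _pair(rng, truth, D=(12000, 4000))
        f = fit(pair, "GammaZero", seed=0)
        dnds = (pair.D_nonsyn / pair.L_nonsyn) / (pair.D_syn / pair.L_syn)
        assert f.omega_a + f.omega_na == pytest.approx(dnds, abs=1e-9)
        assert f.alpha == pytest.approx(f.omega_a / dnds, abs=1e-9)

    def test_alpha_zero_when_observed_matches_expected(self, rng):
        truth = DFEModel("GammaZero", shape=0.4, s_mean=1000)
        pair = _pair(rng, truth)
        f = fit(pair, "GammaZero", seed=0, with_alpha=False)
        w_na = f.model.omega_na()
        # construct divergence exactly at the model expectation
        Ds = 10000.0
        Dn = Ds * (pair.L_nonsyn / pair.L_syn) * w_na
        alpha, omega_a, omega_na = alpha_omega(f, Ds, Dn, pair.L_syn, pair.L_nonsyn)
        assert alpha == pytest.approx(0.0, abs=1e-9)
        assert omega_a == pytest.approx(0.0, abs=1e-12)

    def test_requires_divergence(self, rng):
        pair = _pair(rng)
        f = fit(pair, "GammaZero", seed=0, with_alpha=False)
        with pytest.raises(ValueError):
            alpha_omega(f, 0.0, 10.0, pair.L_syn, pair.L_nonsyn)


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(77)
    truth = DFEModel("GammaZero", shape=0.4, s_mean=2000)
    p = 0.002
    syn, nonsyn = simulate_sfs_counts(
        rng, None, 3e5, 8e5, 0.005, 20, dfe=truth, p_adapt=p, s_adv=25.0
    )
    Ds, Dn = simulate_divergence_counts(
        rng, 3e5, 8e5, d=0.08, dfe=truth, p_adapt=p, s_adv=25.0
    )
    pair = SFSPair(ALL, 20, syn, nonsyn, 3e5, 8e5, D_syn=Ds, D_nonsyn=Dn)
    return fit(pair, "GammaZero", seed=0)


class TestProfileCI:
    def test_contains_mle(self, fitted):
        ci = profile_ci(fitted, "alpha")
        assert ci.low <= fitted.alpha <= ci.high
        ci_w = profile_ci(fitted, "omega_a")
        assert ci_w.low <= fitted.omega_a <= ci_w.high

    def test_more_data_shrinks_ci(self, fitted):
        rng = np.random.default_rng(78)
        truth = DFEModel("GammaZero", shape=0.4, s_mean=2000)
        big = 20.0
        syn, nonsyn = simulate_sfs_counts(
            rng, None, big * 3e5, big * 8e5, 0.005, 20, dfe=truth
        )
        Ds, Dn = simulate_divergence_counts(
            rng, big * 3e5, big * 8e5, d=0.08, dfe=truth
        )
        pair = SFSPair(ALL, 20, syn, nonsyn, big * 3e5, big * 8e5, D_syn=Ds, D_nonsyn=Dn)
        f_big = fit(pair, "GammaZero", seed=0)
        ci_small = profile_ci(fitted, "alpha")
        ci_big = profile_ci(f_big, "alpha")
        assert (ci_big.high - ci_big.low) < (ci_small.high - ci_small.low)
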