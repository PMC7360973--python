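"""Binomial composition model and global kinetic fit: oracles and identities."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trimerfit import synthetic
from trimerfit.mixture import (
    MixRatio, MixtureComposition, KineticTrace, GlobalKineticModel,
    trimer_composition, mixture_signal, null_prediction, global_fit_mixture,
    compare_models,
)
from trimerfit.models import delay_exponential


def enumeration_composition(a, b):
    """Brute-force oracle: enumerate ordered monomer triples with probabilities
    proportional to the mixing ratio, tally accessible-site counts."""
    p = a / (a + b)
    probs = {"w": p, "m": 1 - p}
    counts = {3: 0.0, 2: 0.0, 1: 0.0, 0: 0.0}
    for triple in itertools.product("wm", repeat=3):
        weight = np.prod([probs[x] for x in triple])
        counts[triple.count("w")] += weight
    return counts


class TestComposition:
    def test_two_to_one_ratio_printed_fractions(self):
        # 2:1 wild-type:mutant gives 29.6 / 44.4 / 22.2 / 3.7 percent
        c = trimer_composition((2, 1))
        assert c.f3 == pytest.approx(0.2963, abs=5e-5)
        assert c.f2 == pytest.approx(0.4444, abs=5e-5)
        assert c.f1 == pytest.approx(0.2222, abs=5e-5)
        assert c.f0 == pytest.approx(0.0370, abs=5e-5)

    def test_pure_wild_type(self):
        c = trimer_composition((1, 0))
        assert (c.f3, c.f2, c.f1, c.f0) == (1.0, 0.0, 0.0, 0.0)

    def test_one_to_one_enumeration(self):
        # all 2^3 ordered triples at p = 1/2
        c = trimer_composition((1, 1))
        assert (c.f3, c.f2, c.f1, c.f0) == pytest.approx((0.125, 0.375, 0.375, 0.125))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = rng.uniform(0, 5, 2)
            if a + b == 0:
                continue
            c = trimer_composition((a, b))
            oracle = enumeration_composition(a, b)
            for f, n in ((c.f3, 3), (c.f2, 2), (c.f1, 1), (c.f0, 0)):
                assert f == pytest.approx(oracle[n], abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(a=st.floats(0.0, 10.0), b=st.floats(0.0, 10.0))
    def test_exchange_symmetry_and_normalization(self, a, b):
        if a + b <= 0:
            return
        c = trimer_composition((a, b))
        r = trimer_composition((b, a))
        assert (c.f3, c.f2, c.f1, c.f0) == pytest.approx((r.f0, r.f1, r.f2, r.f3))
        assert c.f3 + c.f2 + c.f1 + c.f0 == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(ValueError):
            MixRatio(0, 0)


def _model(k1=0.005, k2=0.02, k3=0.05, y_max=200.0, y_0=80.0, t0=5.0, variant="full"):
    return GlobalKineticModel(k1=k1, k2=k2, k3=k3, y_max=[y_max], y_0=[y_0],
                              t0=[t0], variant=variant)


class TestMixtureSignal:
    def test_undissociable_homotrimer_constant(self):
        comp = MixtureComposition(f3=0, f2=0, f1=0, f0=1)
        t = np.linspace(0, 200, 50)
        assert mixture_signal(t, _model(), comp) == pytest.approx(
            np.full(50, 200.0))

    def test_pure_wild_type_reduces_to_delay_exponential(self):
        comp = MixtureComposition(f3=1, f2=0, f1=0, f0=0)
        t = np.linspace(0, 150, 80)
        expected = delay_exponential(t, 200.0, 80.0, 0.05, 5.0)
        assert mixture_signal(t, _model(), comp) == pytest.approx(expected)

    def test_equal_rates_scale_by_decaying_fraction(self):
        # k1=k2=k3=k collapses to one exponential with amplitude (1 - f0)
        comp = trimer_composition((1, 2))
        k = 0.03
        t = np.linspace(0, 150, 60)
        y = mixture_signal(t, _model(k, k, k), comp)
        single = delay_exponential(t, 200.0, 80.0, k, 5.0)
        expected = 80.0 + (200.0 - 80.0) * (
            comp.f0 + (1 - comp.f0) * (single - 80.0) / 120.0)
        assert y == pytest.approx(expected, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(0.0, 5.0), b=st.floats(0.0, 5.0), t=st.floats(0.0, 5.0))
    def test_amplitude_conserved_during_lag(self, a, b, t):
        if a + b <= 0:
            return
        comp = trimer_composition((a, b))
        assert mixture_signal(t, _model(), comp) == pytest.approx(200.0)


class TestNullPrediction:
    def test_single_site_null_pure_wt_equals_full_curve(self):
        comp = trimer_composition((1, 0))
        t = np.linspace(0, 120, 40)
        y = null_prediction("single_site_null", comp, 0.05, 200.0, 80.0, 5.0, t)
        assert y == pytest.approx(delay_exponential(t, 200.0, 80.0, 0.05, 5.0))

    def test_three_sites_null_decaying_amplitude(self):
        comp = trimer_composition((1, 2))
        y_inf = null_prediction("three_sites_null", comp, 0.05, 200.0, 80.0, 0.0,
                                np.array([1e9]))[0]
        amp_fraction = (200.0 - y_inf) / 120.0
        assert amp_fraction == pytest.approx((1 / 3) ** 3, abs=1e-9)

    def test_single_site_null_decaying_amplitude(self):
        comp = trimer_composition((1, 2))
        y_inf = null_prediction("single_site_null", comp, 0.05, 200.0, 80.0, 0.0,
                                np.array([1e9]))[0]
        assert (200.0 - y_inf) / 120.0 == pytest.approx(1 - (2 / 3) ** 3, abs=1e-9)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            null_prediction("bogus", trimer_composition((1, 1)), 0.05,
                            200.0, 80.0, 0.0, np.arange(10.0))


class TestGlobalFit:
    def test_noiseless_round_trip_exact(self):
        traces = synthetic.gen_mixture_experiment(
            ratios=((1, 0), (2, 1), (1, 1), (1, 2)), noise_sd=0.0)
        fit = global_fit_mixture(traces)
        assert fit.success
        m = fit.model
        assert m.k1 == pytest.approx(0.005, rel=1e-5)
        assert m.k2 == pytest.approx(0.02, rel=1e-5)
        assert m.k3 == pytest.approx(0.05, rel=1e-5)
        assert m.t0[0] == pytest.approx(5.0, rel=1e-4)

    def test_per_trace_amplitudes_still_supported(self):
        traces = synthetic.gen_mixture_experiment(
            ratios=((1, 0), (2, 1), (1, 1), (1, 2)), noise_sd=0.0)
        fit = global_fit_mixture(traces, share_amplitudes=False)
        assert fit.success
        assert fit.model.k3 == pytest.approx(0.05, rel=1e-5)
        assert fit.model.y_max == pytest.approx([200.0] * len(traces), rel=1e-4)
        assert fit.model.y_0 == pytest.approx([80.0] * len(traces), rel=1e-3)

    def test_single_pure_wt_trace_flags_unidentifiable_rates(self):
        traces = synthetic.gen_mixture_experiment(ratios=((1, 0),), noise_sd=0.0)
        fit = global_fit_mixture(traces)
        assert fit.model.k3 == pytest.approx(0.05, rel=1e-4)
        assert set(fit.under_determined) == {"k1", "k2"}
        assert np.isinf(fit.stderr["k1"]) and np.isinf(fit.stderr["k2"])

    def test_rate_ordering_preserved_in_noisy_fits(self):
        ok = 0
        for seed in range(10):
            traces = synthetic.gen_mixture_experiment(noise_sd=0.02 * 120, seed=seed)
            m = global_fit_mixture(traces).model
            ok += m.k1 < m.k2 < m.k3
        assert ok == 10


class TestCompareModels:
    def test_full_model_preferred_on_full_data(self):
        traces = synthetic.gen_mixture_experiment(noise_sd=0.02 * 120, seed=11)
        table = compare_models(traces).set_index("variant")
        assert table.loc["full", "best"]
        assert table.loc["full", "aic"] < table.loc["single_site_null", "aic"]

    def test_equal_rates_make_single_site_null_competitive(self):
        traces = synthetic.gen_mixture_experiment(rates=(0.03, 0.03, 0.03),
                                                  noise_sd=0.02 * 120, seed=3)
        table = compare_models(traces).set_index("variant")
        # identical likelihoods, fewer parameters: the null is within 2 AIC units
        assert table.loc["single_site_null", "aic"] <= table.loc["full", "aic"] + 2.0

    def test_three_sites_null_data_preferred(self):
        t = np.arange(0.0, 101.0)
        rng = np.random.default_rng(7)
        traces = []
        for a, b in synthetic.DEFAULT_RATIOS:
            comp = trimer_composition((a, b))
            y = null_prediction("three_sites_null", comp, 0.05, 200.0, 80.0, 5.0, t)
            traces.append(KineticTrace(t.copy(), y + rng.normal(0, 2.4, t.size),
                                       MixRatio(a, b)))
        table = compare_models(traces).set_index("variant")
        assert table.loc["three_sites_null", "best"]
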