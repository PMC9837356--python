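import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simepet.blood import (
    BloodSample,
    BPRModel,
    HillModel,
    InputFunction,
    fit_bpr,
    fit_parent_fraction,
    metabolite_correct,
    scale_idif,
    venous_arterial_agreement,
)
from simepet.exceptions import (
    DegenerateRegressionError,
    InsufficientDataError,
    InvalidSampleError,
    ModelDomainError,
    ScalingError,
)

# manual sampling times used in the paired venous/arterial protocol
SAMPLE_TIMES = [2.5, 7, 12, 20, 30, 45, 60, 90, 120, 180]


def make_samples(times, bpr_fn, pf_fn=None, plasma=10.0, site="venous"):
    out = []
    for t in times:
        pf = None if pf_fn is None else pf_fn(t)
        out.append(
            BloodSample(
                time=t,
                whole_blood=plasma * bpr_fn(t),
                plasma=plasma,
                parent_fraction=pf,
                site=site,
            )
        )
    return out


class TestFitBPR:
    def test_constant_ratio_recovered_exactly(self):
        samples = make_samples(SAMPLE_TIMES, lambda t: 0.85)
        model = fit_bpr(samples)
        t = np.linspace(min(SAMPLE_TIMES), max(SAMPLE_TIMES), 200)
        np.testing.assert_allclose(model(t), 0.85, rtol=1e-6)
        assert model.rss < 1e-10

    def test_noiseless_biexponential_self_consistency(self):
        true = lambda t: 0.5 * np.exp(-0.1 * t) + 0.7
        samples = make_samples(SAMPLE_TIMES, true)
        model = fit_bpr(samples)
        assert model.rss < 1e-10
        t = np.array(SAMPLE_TIMES)
        np.testing.assert_allclose(model(t), true(t), rtol=1e-4)
        # A2*exp(-lam2 t) term carries the 0.7 plateau
        assert model.A1 == pytest.approx(0.5, rel=1e-3)
        assert model.lam1 == pytest.approx(0.1, rel=1e-3)

    def test_zero_plasma_rejected(self):
        samples = make_samples(SAMPLE_TIMES, lambda t: 1.0)
        bad = BloodSample(time=5.0, whole_blood=1.0, plasma=0.0)
        with pytest.raises(InvalidSampleError):
            fit_bpr(samples + [bad])

    def test_too_few_samples(self):
        samples = make_samples(SAMPLE_TIMES[:3], lambda t: 1.0)
        with pytest.raises(InsufficientDataError):
            fit_bpr(samples)

    def test_rate_ordering_invariant(self):
        samples = make_samples(SAMPLE_TIMES, lambda t: 0.4 * np.exp(-0.3 * t) + 0.6)
        model = fit_bpr(samples)
        assert model.lam1 >= model.lam2 >= 0


class TestFitParentFraction:
    def test_fitted_curve_is_one_at_time_zero(self):
        hill = HillModel(0.2, 2.0, 30.0)
        samples = make_samples(SAMPLE_TIMES, lambda t: 1.0, pf_fn=lambda t: float(hill(t)))
        fitted = fit_parent_fraction(samples)
        assert fitted(0.0) == pytest.approx(1.0)

    def test_noiseless_recovery(self):
        true = HillModel(0.1, 1.5, 50.0)
        samples = make_samples(SAMPLE_TIMES, lambda t: 1.0, pf_fn=lambda t: float(true(t)))
        fitted = fit_parent_fraction(samples)
        assert fitted.a == pytest.approx(true.a, rel=1e-3)
        assert fitted.b == pytest.approx(true.b, rel=1e-3)
        assert fitted.c == pytest.approx(true.c, rel=1e-3)

    def test_all_unmetabolized(self):
        samples = make_samples(SAMPLE_TIMES, lambda t: 1.0, pf_fn=lambda t: 1.0)
        fitted = fit_parent_fraction(samples)
        t = np.linspace(0, 180, 60)
        np.testing.assert_allclose(fitted(t), 1.0, atol=1e-6)
        assert fitted.rss < 1e-10

    def test_requires_fractions(self):
        samples = make_samples(SAMPLE_TIMES, lambda t: 1.0)
        with pytest.raises(InsufficientDataError):
            fit_parent_fraction(samples)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.floats(0.0, 1.0),
        b=st.floats(0.1, 5.0),
        c=st.floats(0.5, 500.0),
    )
    def test_hill_monotone_non_increasing(self, a, b, c):
        f = HillModel(a, b, c)
        t = np.linspace(0.0, 300.0, 1500)
        vals = f(t)
        assert (np.diff(vals) <= 1e-12).all()
        assert vals[0] == pytest.approx(1.0)
        assert vals[-1] >= a - 1e-9


def uniform_input(t_end=95.0, wb=lambda t: np.exp(-0.01 * t) + 0.5):
    t = np.arange(0.0, t_end + 1e-9, 1.0 / 60.0)
    return InputFunction(t, wb(t), provenance="IDIF")


class TestMetaboliteCorrect:
    def test_identity_when_bpr_and_fraction_are_one(self):
        inp = uniform_input()
        out = metabolite_correct(inp, BPRModel(1.0, 0.0, 0.0, 0.0), HillModel(1.0, 1.0, 1.0))
        np.testing.assert_allclose(out.plasma_parent, inp.whole_blood, rtol=1e-12)

    def test_scalar_algebra(self):
        # constant BPR = 2 and f = 0.5 -> parent is a quarter of whole blood
        class Half:
            def __call__(self, t):
                return np.full_like(np.asarray(t, float), 0.5)

        inp = uniform_input()
        out = metabolite_correct(inp, BPRModel(2.0, 0.0, 0.0, 0.0), Half())
        np.testing.assert_allclose(out.plasma_parent, inp.whole_blood / 4.0, rtol=1e-12)

    def test_pointwise_against_hand_computation(self):
        bpr = BPRModel(0.5, 0.7, 0.1, 0.0)
        hill = HillModel(0.1, 1.5, 50.0)
        inp = uniform_input()
        out = metabolite_correct(inp, bpr, hill)
        i30 = int(np.argmin(np.abs(inp.time - 30.0)))
        t30 = inp.time[i30]
        expected = inp.whole_blood[i30] / float(bpr(t30)) * float(hill(t30))
        assert out.plasma_parent[i30] == pytest.approx(expected, rel=1e-12)

    def test_linearity_under_input_scaling(self):
        bpr = BPRModel(0.5, 0.7, 0.1, 0.0)
        hill = HillModel(0.1, 1.5, 50.0)
        inp = uniform_input()
        base = metabolite_correct(inp, bpr, hill).plasma_parent
        scaled = metabolite_correct(inp.scaled(3.0), bpr, hill).plasma_parent
        np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-12)

    def test_zero_bpr_rejected(self):
        # a ratio model that collapses to zero on the grid must be refused
        class ZeroLate:
            def __call__(self, t):
                return np.where(np.asarray(t, float) < 50.0, 1.0, 0.0)

        inp = uniform_input()
        with pytest.raises(ModelDomainError):
            metabolite_correct(inp, ZeroLate(), HillModel(1.0, 1.0, 1.0))


class TestScaleIdif:
    def _venous_at(self, idif, times, factor):
        return [
            BloodSample(time=t, whole_blood=factor * float(idif.wb_at(t)), plasma=1.0)
            for t in times
        ]

    def test_matching_samples_give_unit_scale(self):
        idif = uniform_input()
        venous = self._venous_at(idif, (45, 60, 90), 1.0)
        scaled, s = scale_idif(idif, venous)
        assert s == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(scaled.whole_blood, idif.whole_blood)

    def test_doubled_samples_give_scale_two(self):
        idif = uniform_input()
        venous = self._venous_at(idif, (45, 60, 90), 2.0)
        _, s = scale_idif(idif, venous)
        assert s == pytest.approx(2.0, abs=1e-12)

    def test_closed_form_scalar(self):
        # venous (3.1, 2.0, 1.4) against idif (1.5, 1.0, 0.7):
        # s = (3.1*1.5 + 2.0*1.0 + 1.4*0.7) / (1.5^2 + 1^2 + 0.7^2) = 7.63/3.74
        t = np.arange(0.0, 95.0 + 1e-9, 1.0 / 60.0)
        wb = np.interp(t, [0, 45, 60, 90, 95], [2.0, 1.5, 1.0, 0.7, 0.6])
        idif = InputFunction(t, wb, provenance="IDIF")
        venous = [
            BloodSample(time=45, whole_blood=3.1, plasma=1.0),
            BloodSample(time=60, whole_blood=2.0, plasma=1.0),
            BloodSample(time=90, whole_blood=1.4, plasma=1.0),
        ]
        _, s = scale_idif(idif, venous)
        assert s == pytest.approx(7.63 / 3.74, rel=1e-12)

    def test_idempotent_after_application(self):
        idif = uniform_input()
        venous = self._venous_at(idif, (45, 60, 90), 1.7)
        scaled, s1 = scale_idif(idif, venous)
        _, s2 = scale_idif(scaled, venous)
        assert s1 == pytest.approx(1.7)
        assert s2 == pytest.approx(1.0, abs=1e-12)

    def test_missing_samples_raise(self):
        idif = uniform_input()
        venous = self._venous_at(idif, (45, 60), 1.0)
        with pytest.raises(ScalingError, match="90"):
            scale_idif(idif, venous)

    def test_zero_idif_degenerate(self):
        t = np.arange(0.0, 95.0 + 1e-9, 1.0 / 60.0)
        idif = InputFunction(t, np.zeros_like(t), provenance="IDIF")
        venous = [BloodSample(time=x, whole_blood=1.0, plasma=1.0) for x in (45, 60, 90)]
        with pytest.raises(ScalingError):
            scale_idif(idif, venous)


class TestVenousArterialAgreement:
    def test_identical_pairs(self):
        pairs = [(x, x) for x in (0.6, 0.8, 1.0, 1.2)]
        stats = venous_arterial_agreement(pairs)
        assert stats.slope == pytest.approx(1.0)
        assert stats.intercept == pytest.approx(0.0, abs=1e-12)
        assert stats.r_squared == pytest.approx(1.0)
        assert stats.p_slope_vs_one == pytest.approx(1.0)

    def test_exact_double_line(self):
        pairs = [(2.0 * x, x) for x in range(1, 11)]  # venous = 2 * arterial
        stats = venous_arterial_agreement(pairs)
        assert stats.slope == pytest.approx(2.0)
        assert stats.r_squared == pytest.approx(1.0)
        assert stats.p_slope_vs_one < 0.05

    def test_pvalue_matches_ols_oracle(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(7)
        art = np.linspace(0.5, 1.5, 10)
        ven = 0.94 * art + 0.06 + rng.normal(0, 0.03, art.size)
        stats = venous_arterial_agreement(list(zip(ven, art)))
        X = statsmodels.add_constant(art)
        fitres = statsmodels.OLS(ven, X).fit()
        assert stats.slope == pytest.approx(fitres.params[1], rel=1e-10)
        t_oracle = (fitres.params[1] - 1.0) / fitres.bse[1]
        from scipy import stats as sps

        p_oracle = 2 * sps.t.sf(abs(t_oracle), df=art.size - 2)
        assert stats.p_slope_vs_one == pytest.approx(p_oracle, rel=1e-10)

    def test_degenerate_arterial(self):
        with pytest.raises(DegenerateRegressionError):
            venous_arterial_agreement([(1.0, 0.5), (1.1, 0.5), (0.9, 0.5)])

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            venous_arterial_agreement([(1.0, 1.0), (2.0, 2.0)])
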