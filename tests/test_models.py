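"""Forward-model tests: Cole–Cole evaluation, temperature laws, crossover,
and the packaged literature registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import thermodiel as td
from thermodiel.models import EPS0

from conftest import oracle_eps


def single_pole(eps_inf, sigma_s, delta, tau, alpha):
    return td.ColeColeModel(eps_inf, sigma_s, (td.ColeColePole(delta, tau, alpha),))


class TestEvaluate:
    def test_pole_free_identity(self):
        m = td.ColeColeModel(eps_inf=4.0, sigma_s=0.0)
        eps = m.evaluate([1e9, 5e9, 40e9])
        assert np.all(eps.real == 4.0)
        assert np.all(eps.imag == 0.0)

    def test_gamma_pole_matches_scalar_oracle(self):
        m = single_pole(4.00, 0.20, 50.00, 7.23e-12, 0.10)
        got = m.evaluate(2.45e9)
        want = oracle_eps(4.00, 0.20, [(50.00, 7.23e-12, 0.10)], 2.45e9)
        assert abs(got - want) / abs(want) < 1e-12

    def test_alpha_zero_reduces_to_debye(self, log_grid):
        m = single_pole(4.0, 0.7, 50.0, 8e-12, 0.0)
        w = 2 * np.pi * log_grid
        debye = 4.0 + 50.0 / (1 + 1j * w * 8e-12) + 0.7 / (1j * w * EPS0)
        got = m.evaluate(log_grid)
        assert np.max(np.abs(got - debye) / np.abs(debye)) < 1e-12

    def test_vectorized_equals_scalar_loop(self, log_grid, literature):
        m = literature["Gabriel"]
        grid_eval = m.evaluate(log_grid)
        scalar_eval = np.array([m.evaluate(f) for f in log_grid])
        assert np.max(np.abs(grid_eval - scalar_eval)) < 1e-12

    def test_output_length_matches_input(self, literature):
        for n in (1, 7, 1581):
            f = np.linspace(0.5e9, 40e9, n)
            assert literature["Peyman"].evaluate(f).shape == (n,)

    @pytest.mark.parametrize("bad", [0.0, -1e9, np.nan])
    def test_nonpositive_frequency_rejected(self, bad):
        m = td.ColeColeModel(4.0)
        with pytest.raises(ValueError):
            m.evaluate([1e9, bad])

    def test_nan_parameter_rejected(self):
        with pytest.raises(ValueError):
            td.ColeColeModel(eps_inf=float("nan"))
        with pytest.raises(ValueError):
            td.ColeColePole(50.0, float("nan"), 0.1)


class TestLimits:
    def test_high_frequency_limit(self, literature):
        # alpha-broadened poles decay only as w^(alpha-1), so the probe
        # frequency must sit far above every relaxation frequency
        for m in literature.values():
            eps = m.evaluate(1e16)
            assert abs(eps.real - m.eps_inf) < 1e-3
            probes = np.geomspace(1e13, 1e16, 20)
            gap = np.abs(m.evaluate(probes).real - m.eps_inf)
            assert np.all(np.diff(gap) < 0)

    def test_low_frequency_conductivity_limit(self):
        m = td.ColeColeModel(eps_inf=4.0, sigma_s=1.3)
        f = 1.0
        eps_im = -m.evaluate(f).imag
        assert abs(2 * np.pi * f * EPS0 * eps_im - 1.3) / 1.3 < 1e-9

    def test_static_limit_closed_form(self, literature):
        for m in literature.values():
            m0 = td.ColeColeModel(m.eps_inf, 0.0, m.poles)
            static = m.eps_inf + sum(p.delta_eps for p in m.poles)
            got = m0.evaluate(1e-6).real
            assert abs(got - static) / static < 1e-6

    def test_passivity_on_band(self, literature, log_grid):
        for m in literature.values():
            assert np.all(-m.evaluate(log_grid).imag >= 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    eps_inf=st.floats(0.5, 20),
    sigma_s=st.floats(0, 5),
    delta=st.floats(1, 100),
    log_tau=st.floats(-12, -9),
    alpha=st.floats(0, 0.49),
)
def test_random_single_pole_is_passive_and_matches_oracle(
    eps_inf, sigma_s, delta, log_tau, alpha
):
    tau = 10.0**log_tau
    m = single_pole(eps_inf, sigma_s, delta, tau, alpha)
    grid = np.geomspace(0.5e9, 40e9, 25)
    eps = m.evaluate(grid)
    assert np.all(-eps.imag >= 0)
    for f in (grid[0], grid[12], grid[-1]):
        want = oracle_eps(eps_inf, sigma_s, [(delta, tau, alpha)], f)
        assert abs(m.evaluate(f) - want) <= 1e-12 * abs(want)


class TestRelaxationFrequency:
    def test_delta_pole_printed_value(self, literature):
        pole = literature["Gabriel"].poles[1]
        assert pole.tau == 353.68e-9
        f_mhz = td.relaxation_frequency(pole) / 1e6
        assert round(f_mhz, 2) == 0.45

    def test_analytic_unit_case(self):
        assert td.relaxation_frequency(td.ColeColePole(1.0, 1 / (2 * math.pi), 0.0)) == 1.0

    def test_matches_direct_division(self, literature):
        pole = literature["Gabriel"].poles[0]
        assert td.relaxation_frequency(pole) == 1.0 / (2 * math.pi * 7.23e-12)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            td.relaxation_frequency(0.0)


class TestTemperatureModel:
    def test_sigma_s_at_37_matches_printed(self, published1):
        m = td.model_at_temperature(published1, 37.0)
        assert abs(m.sigma_s - 2.4126) < 1e-12
        assert round(m.sigma_s, 2) == 2.41

    def test_alpha_at_37_matches_printed(self, published1):
        m = td.model_at_temperature(published1, 37.0)
        assert abs(m.poles[0].alpha - 0.1128) < 1e-12
        assert round(m.poles[0].alpha, 2) == 0.11

    def test_tau_converted_to_seconds(self, published1):
        tau = td.model_at_temperature(published1, 37.0).poles[0].tau
        assert tau == pytest.approx((11.7765 - 0.1243 * 37.0) * 1e-12, rel=1e-12)

    def test_zero_slope_law_is_temperature_independent(self):
        laws = tuple(
            td.TemperatureParameterLaw(name, 1, (v, 0.0))
            for name, v in [
                ("eps_inf", 4.0), ("sigma_s", 0.5), ("delta_eps", 50.0),
                ("tau", 8.0), ("alpha", 0.1),
            ]
        )
        tm = td.TemperatureColeColeModel(laws)
        d1 = tm.at_temperature(20.0).to_dict()
        d2 = tm.at_temperature(45.0).to_dict()
        d1.pop("label"), d2.pop("label")
        assert d1 == d2

    def test_strict_mode_rejects_out_of_range(self, published1):
        with pytest.raises(ValueError):
            td.model_at_temperature(published1, 50.0)
        with pytest.warns(UserWarning):
            td.model_at_temperature(published1, 50.0, mode="warn")

    def test_law_coefficient_count_enforced(self):
        with pytest.raises(ValueError):
            td.TemperatureParameterLaw("alpha", 1, (0.1, 0.0, 0.0))

    def test_unphysical_law_rejected_at_construction(self):
        # alpha hits 1 inside the range
        with pytest.raises(ValueError):
            td.TemperatureParameterLaw("alpha", 1, (0.0, 0.03))

    def test_all_five_laws_required(self, published1):
        with pytest.raises(ValueError):
            td.TemperatureColeColeModel(published1.laws[:4])

    def test_json_round_trip(self, published1, tmp_path):
        path = tmp_path / "model.json"
        published1.to_json(path)
        back = td.TemperatureColeColeModel.from_json(path)
        assert back.to_dict() == published1.to_dict()


class TestCrossover:
    def test_published_model_near_six_and_a_half_GHz(self, published1):
        f = td.crossover_frequency(published1, 20.0, 45.0, 0.5e9, 40e9)
        assert abs(f / 1e9 - 6.5) < 0.5

    def test_agrees_with_dense_grid_argmin(self, published1):
        f = td.crossover_frequency(published1, 20.0, 45.0, 0.5e9, 40e9)
        grid = np.arange(0.5e9, 40e9 + 5e5, 1e6)
        m1 = published1.at_temperature(20.0).evaluate(grid).real
        m2 = published1.at_temperature(45.0).evaluate(grid).real
        brute = grid[np.argmin(np.abs(m1 - m2))]
        assert abs(f - brute) <= 1e6

    def test_identical_curves_yield_none(self):
        laws = tuple(
            td.TemperatureParameterLaw(name, 1, (v, 0.0))
            for name, v in [
                ("eps_inf", 4.0), ("sigma_s", 0.5), ("delta_eps", 50.0),
                ("tau", 8.0), ("alpha", 0.1),
            ]
        )
        tm = td.TemperatureColeColeModel(laws)
        assert td.crossover_frequency(tm, 20.0, 45.0, 0.5e9, 40e9) is None

    def test_double_crossing_raises_ambiguity(self):
        # engineered to intersect twice on the band: the cold curve starts
        # slightly lower and relaxes later, so the difference runs - + -
        values_T1 = {"eps_inf": 4.0, "sigma_s": 0.0, "delta_eps": 51.0,
                     "tau": 18.0, "alpha": 0.0}
        values_T2 = {"eps_inf": 6.0, "sigma_s": 0.0, "delta_eps": 50.0,
                     "tau": 30.0, "alpha": 0.0}
        laws = []
        for name in values_T1:
            p1 = (values_T2[name] - values_T1[name]) / 10.0
            p0 = values_T1[name] - p1 * 20.0
            laws.append(td.TemperatureParameterLaw(name, 1, (p0, p1), (20.0, 30.0)))
        tm = td.TemperatureColeColeModel(tuple(laws))
        with pytest.raises(td.AmbiguousCrossoverError) as err:
            td.crossover_frequency(tm, 20.0, 30.0, 0.5e9, 40e9)
        assert len(err.value.brackets) >= 2

    def test_pairwise_crossovers_cluster_in_narrow_band(self, published1):
        """Every temperature pair of the published model crosses exactly
        once, and all crossings cluster in a ~1 GHz band around 6.5 GHz —
        the model's point-like counterpart of the broader crossover zone
        seen in measurements."""
        temps = [20.0, 25.0, 30.0, 35.0, 37.0, 40.0, 43.0, 45.0]
        crossings = [
            td.crossover_frequency(published1, t1, t2, 0.5e9, 40e9)
            for i, t1 in enumerate(temps)
            for t2 in temps[i + 1:]
        ]
        crossings = np.array(crossings, dtype=float)
        assert np.all(np.isfinite(crossings))
        assert crossings.min() > 6.0e9
        assert crossings.max() < 7.2e9


class TestLiteratureRegistry:
    def test_exactly_five_entries(self, literature):
        assert len(literature) == 5

    def test_gabriel_delta_pole_as_printed(self, literature):
        g = literature["Gabriel"]
        assert g.eps_inf == 4.00 and g.sigma_s == 0.20
        p2 = g.poles[1]
        assert (p2.delta_eps, p2.tau, p2.alpha) == (7000.0, 353.68e-9, 0.10)

    def test_this_work_entry_as_printed(self, literature):
        m = literature["This work (37 °C)"]
        assert m.eps_inf == 1.23 and m.sigma_s == 2.41
        assert m.poles[0].delta_eps == 53.73
        assert m.poles[0].tau == 7.21e-12
        assert m.poles[0].alpha == 0.11

    def test_two_pole_models_have_two_poles(self, literature):
        assert len(literature["Gabriel"].poles) == 2
        assert len(literature["Ley"].poles) == 2
        for key in ("Peyman", "Abdilla", "This work (37 °C)"):
            assert len(literature[key].poles) == 1
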