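"""The five-dimension endpoint rule: safety gate, bioactivity score, tie-break."""

import numpy as np
import pytest

from dwatch import (
    SBTEFConfig,
    bioactivity_score,
    decide_endpoint,
    energy_and_cost,
    safety_window,
)
from dwatch.errors import ConfigurationError, NoSafeEndpointError, ParameterError

WINDOW = (0.0, 240.0)


class Curve:
    """Callable-by-predict wrapper so plain functions act like fitted curves."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, t):
        return self.fn(np.asarray(t, dtype=float))


def declining_toxin(t):
    # peaks at 40 then falls exponentially; crosses half-peak near 109 min
    return 10.0 * np.minimum(t / 40.0, 1.0) * np.exp(-0.01 * np.maximum(t - 40.0, 0.0))


def plateau_primary(rise_at=90.0, fall_at=160.0, steep=8.0):
    """Flat-topped bump: logistic rise and fall with a genuine plateau."""
    return Curve(lambda t: 100.0 / (1.0 + np.exp(-(t - rise_at) / steep))
                 / (1.0 + np.exp((t - fall_at) / steep)))


def rising(scale=1.0, rate=0.01):
    return Curve(lambda t: scale * (1.0 - np.exp(-rate * t)))


class TestSafetyWindow:
    def test_single_crossing_gives_tail_interval(self):
        iv = safety_window({"tox": Curve(declining_toxin)}, 0.5, WINDOW)
        onset_intervals = [i for i in iv if i[1] == 240.0]
        assert len(onset_intervals) == 1
        t_star = onset_intervals[0][0]
        assert 105.0 <= t_star <= 115.0

    def test_toxin_never_below_threshold_gives_empty_set(self):
        iv = safety_window({"tox": Curve(lambda t: np.full_like(t, 5.0) + 0.001 * t)},
                           0.5, WINDOW)
        assert iv == []

    def test_no_toxics_configured_warns_and_returns_whole_window(self):
        with pytest.warns(UserWarning):
            assert safety_window({}, 0.5, WINDOW) == [WINDOW]

    def test_looser_threshold_never_shrinks_the_window(self):
        """Monotonicity: the safe set grows (by inclusion) with theta."""
        curves = {"tox": Curve(declining_toxin)}

        def total(iv):
            return sum(b - a for a, b in iv)

        def covers(big, small):
            return all(any(a >= a2 - 1e-9 and b <= b2 + 1e-9 for a2, b2 in big)
                       for a, b in small)

        prev = None
        for theta in (0.2, 0.4, 0.6, 0.8):
            iv = safety_window(curves, theta, WINDOW)
            if prev is not None:
                assert total(iv) >= total(prev) - 1e-9
                assert covers(iv, prev)
            prev = iv

    def test_calibrated_co_toxin_window_opens_between_90_and_120(self, co_traces):
        iv = safety_window({"hypaconitine": co_traces["hypaconitine"]}, 0.5, WINDOW)
        tail = [i for i in iv if i[1] >= 239.0]
        assert tail and 90.0 <= tail[0][0] <= 120.0


class TestBioactivityScore:
    def test_full_score_inside_plateau_with_secondaries_at_max(self):
        primary = {"p": plateau_primary()}
        secondary = {"s": Curve(lambda t: np.ones_like(t))}
        assert bioactivity_score(primary, secondary, 125.0) == pytest.approx(1.0)

    def test_gate_upper_edge_from_find_plateau(self):
        from dwatch.fitting import find_plateau

        t = np.arange(0.0, 240.0001, 0.2)
        lo, hi = find_plateau(t, plateau_primary().predict(t), 0.10, 1e-3)
        assert 90.0 < lo < 125.0 < hi < 170.0

    def test_gate_zero_outside_primary_plateau(self):
        primary = {"p": plateau_primary()}
        secondary = {"s": Curve(lambda t: np.ones_like(t))}
        assert bioactivity_score(primary, secondary, 10.0) == 0.0

    def test_empty_active_lists_rejected(self):
        with pytest.raises(ParameterError):
            bioactivity_score({}, {"s": rising()}, 100.0)

    def test_calibrated_co_scenario_prefers_150_over_100(self, co_traces):
        """Later-rising polyphenol/phenolic products reward 150 min over 100."""
        primary = {"benzoylhypaconitine": co_traces["benzoylhypaconitine"]}
        secondary = {cid: co_traces[cid] for cid in
                     ("gallic_acid", "ellagic_acid", "shogaol_6", "zingerone",
                      "pentagalloylglucose")}
        s100 = bioactivity_score(primary, secondary, 100.0)
        s148 = bioactivity_score(primary, secondary, 148.0)
        assert s148 > s100


class TestDecideEndpoint:
    def _curves(self, toxin=declining_toxin):
        return {
            "tox": Curve(toxin),
            "p": plateau_primary(),
            "s1": rising(rate=0.012),
            "s2": rising(scale=3.0, rate=0.008),
        }

    def _config(self, **kw):
        return SBTEFConfig(toxic_ids=["tox"], primary_active_ids=["p"],
                           secondary_active_ids=["s1", "s2"], **kw)

    def _gate(self):
        from dwatch.fitting import find_plateau

        t = np.arange(0.0, 240.0001, 0.2)
        return find_plateau(t, plateau_primary().predict(t), 0.10, 1e-3)

    def test_flat_secondaries_choose_earliest_gated_safe_time(self):
        curves = self._curves()
        curves["s1"] = Curve(lambda t: np.ones_like(t))
        curves["s2"] = Curve(lambda t: np.ones_like(t))
        d = decide_endpoint(curves, self._config())
        gate_lo, _ = self._gate()
        safe_lo = d.safe_window[-1][0]
        expected = np.ceil(max(gate_lo, safe_lo))
        assert d.endpoint_min == pytest.approx(expected, abs=1.0)

    def test_rising_secondaries_push_to_plateau_upper_edge(self):
        """With secondaries strictly increasing over the safe window the
        endpoint is the latest time the primary gate allows."""
        d = decide_endpoint(self._curves(), self._config())
        _, gate_hi = self._gate()
        assert d.endpoint_min == pytest.approx(np.floor(gate_hi), abs=1.0)

    def test_empty_safe_window_raises(self):
        curves = self._curves(toxin=lambda t: np.full_like(t, 5.0) + 0.001 * t)
        with pytest.raises(NoSafeEndpointError):
            decide_endpoint(curves, self._config())

    def test_decision_is_deterministic(self):
        a = decide_endpoint(self._curves(), self._config())
        b = decide_endpoint(self._curves(), self._config())
        assert a.endpoint_min == b.endpoint_min and a.rationale == b.rationale

    def test_stricter_plateau_band_never_gives_earlier_endpoint(self):
        """Shrinking delta tightens the primary gate; the chosen endpoint can
        only move later (or the decision fail)."""
        prev = None
        for delta in (0.30, 0.20, 0.10, 0.05):
            d = decide_endpoint(self._curves(), self._config(delta_bioactivity=delta))
            if prev is not None:
                assert d.endpoint_min >= prev - 1e-9
            prev = d.endpoint_min

    def test_endpoint_lies_inside_safe_window(self):
        d = decide_endpoint(self._curves(), self._config())
        assert any(a - 1e-9 <= d.endpoint_min <= b + 1e-9 for a, b in d.safe_window)

    def test_missing_configured_compound_rejected(self):
        curves = self._curves()
        del curves["s2"]
        with pytest.raises(ConfigurationError):
            decide_endpoint(curves, self._config())


class TestEnergyAndCost:
    def test_zero_time_costs_nothing(self):
        assert energy_and_cost(0.0, SBTEFConfig()) == (0.0, 0.0)

    def test_150_minutes_at_300_watts_is_0p75_kwh(self):
        energy, _ = energy_and_cost(150.0, SBTEFConfig(power_kw=0.3))
        assert energy == pytest.approx(0.75)

    def test_both_outputs_linear_in_time(self):
        cfg = SBTEFConfig()
        e1, c1 = energy_and_cost(70.0, cfg)
        e2, c2 = energy_and_cost(140.0, cfg)
        assert e2 == pytest.approx(2 * e1) and c2 == pytest.approx(2 * c1)

    def test_energy_matches_decision_invariant(self):
        cfg = SBTEFConfig()
        energy, _ = energy_and_cost(150.0, cfg)
        assert energy == cfg.power_kw * 150.0 / 60.0


class TestConfigValidation:
    def test_safety_must_come_first(self):
        with pytest.raises(ConfigurationError):
            SBTEFConfig(weights=("B", "S", "T", "E", "F"))

    @pytest.mark.parametrize("kw", [dict(theta_safety=0.0), dict(theta_safety=1.0),
                                    dict(delta_bioactivity=1.5), dict(power_kw=-1.0)])
    def test_out_of_range_values_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            SBTEFConfig(**kw)
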