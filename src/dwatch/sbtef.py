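"""SBTEF endpoint decision: Safety, Bioactivity, Time, Energy, Financial cost.

The decision is strictly lexicographic, mirroring how the five dimensions
are prioritised in practice:

1. *Safety* is a hard constraint: every toxic compound's fitted curve must
   sit at or below ``theta_safety`` × its own fitted peak.
2. *Bioactivity* is maximised inside the safe window: primary active
   compounds gate the score (it is zero whenever any of them is outside its
   high-efficacy plateau), and secondary actives reward times where their
   curves approach their maxima.
3. *Time*, *energy* and *cost* are all strictly increasing in the endpoint
   at constant heater power, so taking the earliest bioactivity maximiser
   minimises all three simultaneously.

A numeric-weight mode is available for sensitivity analyses but is off by
default; the published reasoning is ordinal, not cardinal.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, NoSafeEndpointError, ParameterError
from .fitting import find_plateau

__all__ = ["SBTEFConfig", "EndpointDecision", "safety_window",
           "bioactivity_score", "decide_endpoint", "energy_and_cost"]

_DIMENSIONS = ("S", "B", "T", "E", "F")

# Default compound roles for the Zhenwu Decoction scenario: the diester
# alkaloid is the toxin; the monoester that holds a mid-decoction plateau is
# the gating active; later-rising polyphenol/phenolic products reward longer
# decoction while they still climb.
_ZWD_TOXIC = ["hypaconitine"]
_ZWD_PRIMARY = ["benzoylhypaconitine"]
_ZWD_SECONDARY = ["gallic_acid", "ellagic_acid", "shogaol_6", "zingerone",
                  "pentagalloylglucose"]


@dataclass
class SBTEFConfig:
    """Thresholds, rates and compound roles for the endpoint decision.

    ``theta_safety`` is the toxin threshold as a fraction of each toxic
    compound's own fitted peak (a signal-relative proxy — no absolute
    pharmacological limit is implied).  ``delta_bioactivity`` is the plateau
    band fraction used for the primary-active gate.
    """

    theta_safety: float = 0.5
    delta_bioactivity: float = 0.10
    power_kw: float = 0.3
    cost_energy_per_kwh: float = 0.6
    cost_labor_per_min: float = 0.05
    toxic_ids: list = field(default_factory=lambda: list(_ZWD_TOXIC))
    primary_active_ids: list = field(default_factory=lambda: list(_ZWD_PRIMARY))
    secondary_active_ids: list = field(default_factory=lambda: list(_ZWD_SECONDARY))
    weights: tuple = _DIMENSIONS
    numeric_weights: dict | None = None
    plateau_s_max: float = 1e-3
    grid_min: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.theta_safety < 1.0:
            raise ConfigurationError("theta_safety must lie in (0, 1)")
        if not 0.0 < self.delta_bioactivity < 1.0:
            raise ConfigurationError("delta_bioactivity must lie in (0, 1)")
        if self.power_kw < 0 or self.cost_energy_per_kwh < 0 or self.cost_labor_per_min < 0:
            raise ConfigurationError("power and cost rates must be >= 0")
        if tuple(self.weights)[0] != "S" or sorted(self.weights) != sorted(_DIMENSIONS):
            raise ConfigurationError(
                "weights must be a permutation of S,B,T,E,F with safety first"
            )

    @classmethod
    def from_yaml(cls, path) -> "SBTEFConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class EndpointDecision:
    """Outcome of the SBTEF rule with its per-dimension scores and rationale."""

    endpoint_min: float
    safe_window: list[tuple[float, float]]
    scores: dict
    rationale: list[str]

    def to_dict(self) -> dict:
        return {
            "endpoint_min": self.endpoint_min,
            "safe_window": [[a, b] for a, b in self.safe_window],
            "scores": self.scores,
            "rationale": self.rationale,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _curve_fn(obj):
    """Accept FitResult-likes (.predict) or ConcentrationTrace-likes (.at)."""
    if hasattr(obj, "predict"):
        return obj.predict
    if hasattr(obj, "at"):
        return obj.at
    if callable(obj):
        return obj
    raise ParameterError(f"cannot evaluate curve object of type {type(obj)!r}")


def _mask_to_intervals(t: np.ndarray, mask: np.ndarray) -> list[tuple[float, float]]:
    intervals = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            intervals.append((float(t[i]), float(t[j])))
            i = j + 1
        else:
            i += 1
    return intervals


def safety_window(toxic_curves: dict, theta_safety: float,
                  window: tuple[float, float], grid_dt: float = 0.2
                  ) -> list[tuple[float, float]]:
    """Times where every toxic compound is at or below theta × its own peak.

    Returned as disjoint closed intervals on a `grid_dt` grid.
    """
    if not 0.0 < theta_safety < 1.0:
        raise ConfigurationError("theta_safety must lie in (0, 1)")
    t0, t1 = window
    t = np.arange(t0, t1 + 1e-9, grid_dt)
    if not toxic_curves:
        warnings.warn("no toxic compounds configured; whole window is 'safe'",
                      stacklevel=2)
        return [(float(t0), float(t1))]
    mask = np.ones(t.size, dtype=bool)
    for cid, curve in toxic_curves.items():
        v = _curve_fn(curve)(t)
        peak = float(np.max(v))
        if peak <= 0:
            raise ParameterError(f"toxic curve {cid!r} has non-positive peak")
        mask &= v <= theta_safety * peak
    return _mask_to_intervals(t, mask)


def bioactivity_score(primary_curves: dict, secondary_curves: dict, t,
                      delta: float = 0.10, window: tuple[float, float] = (0.0, 240.0),
                      s_max: float = 1e-3, grid_dt: float = 0.2):
    """Plateau-gated bioactivity score in [0, 1] at time(s) `t`.

    Zero wherever any primary active sits outside its own high-efficacy
    plateau; otherwise the mean over secondary actives of curve(t)/max.
    """
    if not primary_curves or not secondary_curves:
        raise ParameterError("primary and secondary active lists must be non-empty")
    scalar = np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    tg = np.arange(window[0], window[1] + 1e-9, grid_dt)

    gate = np.ones(t.size, dtype=bool)
    for cid, curve in primary_curves.items():
        v = _curve_fn(curve)(tg)
        plateau = find_plateau(tg, v, delta=delta, s_max=s_max)
        if plateau is None:
            gate &= False
        else:
            gate &= (t >= plateau[0]) & (t <= plateau[1])

    reward = np.zeros(t.size)
    for cid, curve in secondary_curves.items():
        fn = _curve_fn(curve)
        vmax = float(np.max(fn(tg)))
        if vmax > 0:
            reward += np.clip(fn(t) / vmax, 0.0, 1.0)
    reward /= len(secondary_curves)
    out = np.where(gate, reward, 0.0)
    return float(out[0]) if scalar else out


def energy_and_cost(endpoint_min: float, config: SBTEFConfig) -> tuple[float, float]:
    """Energy (kWh) and running cost at constant heater power; both strictly
    increasing in time."""
    if endpoint_min < 0:
        raise ParameterError("endpoint must be >= 0 minutes")
    energy_kwh = config.power_kw * endpoint_min / 60.0
    cost = energy_kwh * config.cost_energy_per_kwh + endpoint_min * config.cost_labor_per_min
    return energy_kwh, cost


def decide_endpoint(curves: dict, config: SBTEFConfig | None = None,
                    window: tuple[float, float] = (0.0, 240.0)) -> EndpointDecision:
    """Lexicographic SBTEF rule on fitted curves.

    Restrict to the safe window; maximise the bioactivity score on a
    1-minute grid; among maximisers (within 1e−6) choose the earliest time,
    which also minimises time, energy and cost.
    """
    config = config or SBTEFConfig()
    rationale = []

    missing = [cid for cid in (config.toxic_ids + config.primary_active_ids
                               + config.secondary_active_ids) if cid not in curves]
    if missing:
        raise ConfigurationError(f"curves missing for configured compounds: {missing}")

    toxic = {cid: curves[cid] for cid in config.toxic_ids}
    safe = safety_window(toxic, config.theta_safety, window)
    rationale.append(
        f"S: toxic curve(s) {sorted(toxic)} <= {config.theta_safety:g} x own fitted "
        f"peak over {['[%g, %g] min' % iv for iv in safe] or 'no interval'}"
    )
    if not safe:
        raise NoSafeEndpointError(
            "no time in the acquisition window satisfies the safety constraint; "
            "consider a longer decoction or review theta_safety"
        )

    primary = {cid: curves[cid] for cid in config.primary_active_ids}
    secondary = {cid: curves[cid] for cid in config.secondary_active_ids}

    grid = []
    for a, b in safe:
        g = np.arange(np.ceil(a / config.grid_min) * config.grid_min, b + 1e-9,
                      config.grid_min)
        grid.append(g)
    grid = np.concatenate(grid) if grid else np.empty(0)
    if grid.size == 0:
        raise NoSafeEndpointError("safe window narrower than the decision grid")

    if config.numeric_weights:
        scores = _numeric_scores(curves, config, grid, window, toxic, primary, secondary)
        rationale.append("numeric-weight mode: maximising weighted sum "
                         f"{config.numeric_weights}")
    else:
        scores = bioactivity_score(primary, secondary, grid,
                                   delta=config.delta_bioactivity, window=window,
                                   s_max=config.plateau_s_max)
    best = float(np.max(scores))
    winners = grid[scores >= best - 1e-6]
    endpoint = float(winners[0])
    rationale.append(
        f"B: bioactivity score maximal ({best:.4f}) at "
        f"{winners.size} grid time(s); primary gate {sorted(primary)}, "
        f"secondary reward {sorted(secondary)}"
    )
    rationale.append(
        f"T/E/F: earliest maximiser chosen ({endpoint:g} min) — time, energy "
        f"and cost are strictly increasing in t, so it minimises all three"
    )

    energy_kwh, cost = energy_and_cost(endpoint, config)
    tox_frac = max(
        float(_curve_fn(c)(np.array([endpoint]))[0]
              / np.max(_curve_fn(c)(np.arange(window[0], window[1] + 1e-9, 0.2))))
        for c in toxic.values()
    ) if toxic else 0.0
    decision = EndpointDecision(
        endpoint_min=endpoint,
        safe_window=[(float(a), float(b)) for a, b in safe],
        scores={
            "safety_toxic_fraction_of_peak": tox_frac,
            "bioactivity": best,
            "time_min": endpoint,
            "energy_kwh": energy_kwh,
            "cost": cost,
        },
        rationale=rationale,
    )
    return decision


def _numeric_scores(curves, config, grid, window, toxic, primary, secondary):
    """Optional cardinal mode: weighted sum of normalised dimension scores."""
    w = {d: float(config.numeric_weights.get(d, 0.0)) for d in _DIMENSIONS}
    tg = np.arange(window[0], window[1] + 1e-9, 0.2)
    s_safety = np.zeros(grid.size)
    for c in toxic.values():
        fn = _curve_fn(c)
        s_safety += 1.0 - fn(grid) / max(float(np.max(fn(tg))), 1e-12)
    s_safety /= max(len(toxic), 1)
    s_bio = bioactivity_score(primary, secondary, grid,
                              delta=config.delta_bioactivity, window=window,
                              s_max=config.plateau_s_max)
    t_norm = (grid - window[0]) / max(window[1] - window[0], 1e-12)
    return (w["S"] * s_safety + w["B"] * s_bio
            + w["T"] * (1 - t_norm) + w["E"] * (1 - t_norm) + w["F"] * (1 - t_norm))
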