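"""Phenomenological decoction kinetics.

Every compound class observed during decoction monitoring is expressed as one
species of a sequential first-order chain with a dissolution front:

    M --k_d--> A --k1--> B --k2--> C

``M`` is the undissolved pool inside the herb tissue, ``A`` the dissolved
parent species, ``B`` its first hydrolysis/conversion product and ``C`` the
terminal product.  Diester alkaloids are monitored as ``A``, monoesters as
``B``, aminoalcohols as ``C``; biphasic intermediates are a ``B`` species with
no initial dissolved fraction, conversion products are ``B`` with ``k2 = 0``,
stable compounds are ``A`` with ``k1 = 0`` and declining glycosides are ``A``
with a slow first-order loss.

Time is measured in minutes from the moment heating starts; the 30-minute
soak that precedes heating is collapsed into ``f0``, the fraction of the
load already dissolved at t = 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ParameterError

__all__ = [
    "KineticClass",
    "System",
    "CascadeParams",
    "ConcentrationTrace",
    "CascadeResult",
    "bateman_abc",
    "simulate_cascade",
    "simulate_biphasic_intermediate",
    "simulate_conversion_pair",
    "simulate_stable",
]


class KineticClass(enum.Enum):
    """Closed set of kinetic behaviours observed across the monitored herbs."""

    DIESTER_TOXIC = "diester_toxic"
    MONOESTER_ACTIVE = "monoester_active"
    AMINOALCOHOL = "aminoalcohol"
    INTERMEDIATE_BIPHASIC = "intermediate_biphasic"
    HYDROLYSIS_PRODUCT_RISING = "hydrolysis_product_rising"
    CONVERSION_PRODUCT = "conversion_product"
    STABLE_DISSOLUTION_ONLY = "stable_dissolution_only"
    DECLINING_GLYCOSIDE = "declining_glycoside"


class System(enum.Enum):
    """Decoction system: one herb alone or the full formula boiled together."""

    SINGLE = "single"
    CO = "co"


@dataclass(frozen=True)
class CascadeParams:
    """Rates and initial state of one dissolution–hydrolysis chain.

    Parameters
    ----------
    M0 : float
        Total load of the parent species (arbitrary concentration units).
    k_d : float
        Dissolution rate, per minute.
    k1, k2 : float
        First and second hydrolysis (or conversion) rates, per minute.
    f0 : float
        Fraction of ``M0`` already dissolved at t=0 (the soak), in [0, 1].
    inhibition : float
        Hydrolysis-inhibition factor for ``k2`` in the co-decoction system:
        the effective rate is ``k2 / inhibition``, so values > 1 slow the
        monoester's further hydrolysis (compatibility effect) and 1 means
        no difference from the single-herb system.
    inhibition_k1 : float
        Same, applied to ``k1``.
    B0, C0 : float
        Amounts of the B and C species already in solution at t=0
        (material formed during the soak, or a pre-existing product pool).
    """

    M0: float
    k_d: float
    k1: float = 0.0
    k2: float = 0.0
    f0: float = 0.15
    inhibition: float = 1.0
    inhibition_k1: float = 1.0
    B0: float = 0.0
    C0: float = 0.0

    def __post_init__(self):
        if self.M0 < 0:
            raise ParameterError(f"M0 must be >= 0, got {self.M0}")
        for name in ("k_d", "k1", "k2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ParameterError(f"{name} must be a finite rate >= 0, got {v}")
        if not 0.0 <= self.f0 <= 1.0:
            raise ParameterError(f"f0 must lie in [0, 1], got {self.f0}")
        if self.inhibition <= 0 or self.inhibition_k1 <= 0:
            raise ParameterError("inhibition modifiers must be > 0")
        if self.B0 < 0 or self.C0 < 0:
            raise ParameterError("B0 and C0 must be >= 0")

    def effective(self, system: System) -> "CascadeParams":
        """Rates actually used in `system`; CO applies the inhibition modifiers."""
        if system == System.CO:
            return replace(
                self,
                k1=self.k1 / self.inhibition_k1,
                k2=self.k2 / self.inhibition,
                inhibition=1.0,
                inhibition_k1=1.0,
            )
        return self


@dataclass
class ConcentrationTrace:
    """Concentration (arbitrary units) versus decoction time for one compound."""

    compound_id: str
    system: System
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ParameterError("times and values must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        if np.any(self.values < -1e-9 * max(1.0, np.max(np.abs(self.values), initial=0.0))):
            raise ParameterError("concentrations must be non-negative")
        # clip tiny negative excursions from the ODE integrator
        self.values = np.maximum(self.values, 0.0)

    def at(self, t) -> np.ndarray:
        """Linear interpolation of the trace at time(s) `t` (minutes)."""
        return np.interp(t, self.times, self.values)


@dataclass
class CascadeResult:
    """All four chain species on a common grid."""

    times: np.ndarray
    M: np.ndarray
    A: ConcentrationTrace
    B: ConcentrationTrace
    C: ConcentrationTrace

    @property
    def total(self) -> np.ndarray:
        return self.M + self.A.values + self.B.values + self.C.values


def _check_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ParameterError("time grid must be a non-empty 1-D array")
    if np.any(grid < 0):
        raise ParameterError("time grid must be non-negative")
    if np.any(np.diff(grid) <= 0):
        raise ParameterError("time grid must be strictly increasing")
    return grid


def bateman_abc(t, A0: float, k1: float, k2: float):
    """Closed-form sequential decay A→B→C with everything dissolved at t=0.

    Returns ``(A, B, C)`` arrays.  The degenerate ``k1 == k2`` case uses the
    ``k1·t·e^{-k1 t}`` limit rather than the 0/0 two-exponential form.
    """
    t = np.asarray(t, dtype=float)
    if k1 < 0 or k2 < 0:
        raise ParameterError("rates must be >= 0")
    A = A0 * np.exp(-k1 * t)
    if k1 == 0:
        B = np.zeros_like(t)
    elif np.isclose(k1, k2, rtol=1e-12, atol=0.0):
        B = A0 * k1 * t * np.exp(-k1 * t)
    else:
        B = A0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    C = A0 - A - B
    return A, B, np.maximum(C, 0.0)


def _cascade_rhs_factory(k_d, k1, k2, transient_loss=None):
    """RHS of the chain ODE.  `transient_loss` = (rate, t_on, t_off) applies an
    extra first-order loss to the C species inside [t_on, t_off] only."""

    def rhs(t, y):
        M, A, B, C = y
        dM = -k_d * M
        dA = k_d * M - k1 * A
        dB = k1 * A - k2 * B
        dC = k2 * B
        if transient_loss is not None:
            rate, t_on, t_off = transient_loss
            if t_on <= t <= t_off:
                dC -= rate * C
        return [dM, dA, dB, dC]

    return rhs


def simulate_cascade(
    params: CascadeParams,
    grid,
    system: System = System.SINGLE,
    compound_ids=("A", "B", "C"),
    transient_loss=None,
    force_numeric: bool = False,
) -> CascadeResult:
    """Solve the dissolution–hydrolysis chain on `grid` (minutes).

    Uses the closed-form Bateman solution when the whole pool is dissolved at
    t=0 (``f0 = 1``) and no transient loss applies; otherwise integrates the
    ODE system with a tight-tolerance Runge–Kutta scheme.
    """
    grid = _check_grid(grid)
    p = params.effective(system)
    Mu0 = p.M0 * (1.0 - p.f0)
    A0 = p.M0 * p.f0

    if p.f0 == 1.0 and transient_loss is None and not force_numeric:
        A, B, C = bateman_abc(grid, A0, p.k1, p.k2)
        M = np.zeros_like(grid)
        B = B + p.B0 * _decay(grid, p.k2)
        C = C + p.C0 + p.B0 * (1.0 - _decay(grid, p.k2))
    else:
        y0 = [Mu0, A0, p.B0, p.C0]
        t_span = (0.0, float(grid[-1]) if grid[-1] > 0 else 1.0)
        sol = solve_ivp(
            _cascade_rhs_factory(p.k_d, p.k1, p.k2, transient_loss),
            t_span,
            y0,
            method="LSODA",
            t_eval=grid if grid[0] >= t_span[0] else None,
            rtol=1e-10,
            atol=1e-12 * max(p.M0 + p.B0 + p.C0, 1.0),
            max_step=5.0,
        )
        if not sol.success:
            raise ParameterError(f"cascade integration failed: {sol.message}")
        M, A, B, C = sol.y

    ida, idb, idc = compound_ids
    return CascadeResult(
        times=grid,
        M=np.maximum(M, 0.0),
        A=ConcentrationTrace(ida, system, grid, A),
        B=ConcentrationTrace(idb, system, grid, B),
        C=ConcentrationTrace(idc, system, grid, C),
    )


def _decay(t, k):
    return np.exp(-k * np.asarray(t, dtype=float))


def simulate_biphasic_intermediate(
    rise_rate: float,
    consume_rate: float,
    source_pool: float,
    grid,
    source_release_rate: float | None = None,
    source_stages: int = 1,
    system: System = System.SINGLE,
    compound_id: str = "intermediate",
) -> ConcentrationTrace:
    """Intermediate of a source→intermediate→product chain: rises then falls.

    With ``source_release_rate`` set, the source is liberated through
    ``source_stages`` sequential first-order delay compartments (an Erlang
    delay) before feeding the intermediate at ``rise_rate``.  A multi-stage
    delay produces the late, sharp interior maximum shown by polyphenol
    intermediates whose own precursors must first hydrolyse step by step; a
    single stage reduces to the plain three-species chain.
    """
    if rise_rate < 0 or consume_rate < 0 or source_pool < 0:
        raise ParameterError("rates and source pool must be >= 0")
    if source_stages < 1:
        raise ParameterError("source_stages must be >= 1")
    grid = _check_grid(grid)
    if source_release_rate is None:
        if source_stages != 1:
            raise ParameterError("source_stages > 1 requires source_release_rate")
        # two-step chain == cascade with everything "dissolved" into A
        p = CascadeParams(M0=source_pool, k_d=0.0, k1=rise_rate, k2=consume_rate, f0=1.0)
        res = simulate_cascade(p, grid, system=system,
                               compound_ids=("src", compound_id, "prod"))
        trace = res.B
        trace.compound_id = compound_id
        return trace
    if source_release_rate < 0:
        raise ParameterError("source_release_rate must be >= 0")

    n = int(source_stages)
    ks, kb, kc = source_release_rate, rise_rate, consume_rate

    # out-rate of delay stage i: ks through the chain, rise_rate into I
    out = np.full(n, ks)
    out[n - 1] = kb

    def rhs(t, y):
        d = np.empty_like(y)
        d[:n] = -out * y[:n]
        d[1:n] += out[: n - 1] * y[: n - 1]
        d[n] = kb * y[n - 1] - kc * y[n]
        d[n + 1] = kc * y[n]
        return d

    y0 = np.zeros(n + 2)
    y0[0] = source_pool
    sol = solve_ivp(rhs, (0.0, float(grid[-1]) if grid[-1] > 0 else 1.0), y0,
                    method="LSODA", t_eval=grid, rtol=1e-10,
                    atol=1e-12 * max(source_pool, 1.0))
    if not sol.success:
        raise ParameterError(f"staged-chain integration failed: {sol.message}")
    return ConcentrationTrace(compound_id, system, grid, np.maximum(sol.y[n], 0.0))


def simulate_conversion_pair(
    precursor_params: CascadeParams,
    conversion_rate: float,
    grid,
    system: System = System.SINGLE,
    ids=("precursor", "product"),
):
    """Thermal conversion precursor→product on top of dissolution.

    Returns ``(precursor_trace, product_trace)``.  The product only
    accumulates (``k2 = 0``); in the co-decoction system the precursor's
    ``inhibition_k1`` modifier damps the conversion.
    """
    if conversion_rate < 0:
        raise ParameterError("conversion_rate must be >= 0")
    p = replace(precursor_params, k1=conversion_rate, k2=0.0)
    res = simulate_cascade(p, grid, system=system, compound_ids=(ids[0], ids[1], "_none"))
    return res.A, res.B


def simulate_stable(params: CascadeParams, grid, system: System = System.SINGLE,
                    compound_id: str = "stable") -> ConcentrationTrace:
    """Dissolution-only trace: monotone rise to the plateau ``M0``."""
    p = replace(params, k1=0.0, k2=0.0)
    res = simulate_cascade(p, grid, system=system, compound_ids=(compound_id, "_b", "_c"))
    return res.A


@dataclass
class ScenarioSpec:
    """Declarative description of one simulated decoction run."""

    name: str
    system: System
    duration_min: float = 240.0
    seed: int = 0
    compounds: list = field(default_factory=list)

    def __post_init__(self):
        if self.duration_min <= 0:
            raise ParameterError("duration must be > 0")
        ids = [c[0].id for c in self.compounds] if self.compounds else []
        if len(ids) != len(set(ids)):
            raise ParameterError("compound ids must be unique")
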