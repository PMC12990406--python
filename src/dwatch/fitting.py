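"""Kinetic curve fitting and summary arithmetic.

Two empirical curve families are fitted to each compound's processed EIC:

* Gaussian sum:    y(x) = Σᵢ aᵢ·exp(−((x−bᵢ)/cᵢ)²),  i = 1..n,  n ≤ 4
* Fourier series:  y(x) = a₀ + Σᵢ [aᵢ·cos(i·w·x) + bᵢ·sin(i·w·x)],  n ≤ 3

Both families are descriptive smoothers, not mechanistic models: they turn
72,000 noisy points into a smooth curve from which initial/peak/final
values, percent changes, trends and plateaus are read.  Model choice is by
adjusted R² with a parsimony tie-break.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize_scalar
from scipy.signal import find_peaks

from .errors import FitError, ParameterError
from .processing import EIC, boxcar_smooth

__all__ = [
    "FitResult", "KineticSummary", "ComparisonResult", "Trend",
    "fit_gaussian_sum", "fit_fourier", "select_model",
    "percent_change", "summarize_kinetics", "compare_modes", "find_plateau",
]


class Trend(enum.Enum):
    RISING = "rising"
    DECLINING = "declining"
    STABLE = "stable"
    BIPHASIC = "biphasic"


@dataclass
class FitResult:
    """A fitted curve family with its goodness-of-fit on the data grid."""

    model: str                 # "gauss" | "fourier"
    n: int                     # model order
    params: np.ndarray         # gauss: [a1,b1,c1,...]; fourier: [a0,w,a1,b1,...]
    r2: float
    adj_r2: float
    rmse: float
    x: np.ndarray
    curve: np.ndarray
    degenerate: bool = False
    compound_id: str = ""

    @property
    def n_params(self) -> int:
        return self.params.size

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "gauss":
            return _gauss_eval(self.params, x)
        if self.model == "fourier":
            return _fourier_eval(self.params, x)
        raise ParameterError(f"unknown model {self.model!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        params = np.asarray(d["params"], dtype=float)
        return cls(d["model"], int(d["n"]), params,
                   np.nan if d.get("r2") is None else float(d["r2"]),
                   np.nan if d.get("adj_r2") is None else float(d["adj_r2"]),
                   float(d.get("rmse", np.nan)), np.empty(0), np.empty(0),
                   degenerate=bool(d.get("degenerate", False)),
                   compound_id=d.get("compound_id", ""))

    def to_dict(self) -> dict:
        return {
            "model": self.model, "n": self.n,
            "params": [float(p) for p in self.params],
            "r2": None if np.isnan(self.r2) else float(self.r2),
            "adj_r2": None if np.isnan(self.adj_r2) else float(self.adj_r2),
            "rmse": float(self.rmse), "degenerate": self.degenerate,
            "compound_id": self.compound_id,
        }


def _gauss_eval(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    y = np.zeros_like(x, dtype=float)
    for a, b, c in params.reshape(-1, 3):
        y += a * np.exp(-(((x - b) / c) ** 2))
    return y


def _fourier_eval(params: np.ndarray, x: np.ndarray) -> np.ndarray:
    a0, w = params[0], params[1]
    y = np.full_like(x, a0, dtype=float)
    for i, (a, b) in enumerate(params[2:].reshape(-1, 2), start=1):
        y += a * np.cos(i * w * x) + b * np.sin(i * w * x)
    return y


def _gof(y: np.ndarray, resid: np.ndarray, n_params: int):
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    n = y.size
    rmse = np.sqrt(sse / n)
    if sst <= 0:
        return np.nan, np.nan, rmse
    r2 = 1.0 - sse / sst
    dof = n - n_params - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / dof if dof > 0 else np.nan
    return r2, adj, rmse


def _is_flat(y: np.ndarray) -> bool:
    scale = max(abs(float(y.max())), abs(float(y.min())), 1e-300)
    return float(y.max() - y.min()) <= 1e-12 * scale


def _xy(eic) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(eic, EIC):
        return eic.times_min, eic.values
    x, y = eic
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def fit_gaussian_sum(eic, n: int, restarts: int = 5, seed: int = 1234) -> FitResult:
    """Nonlinear least squares for an n-component Gaussian sum.

    Initialisation is data driven (largest local maxima for the centres,
    a fraction of the span for the widths); `restarts` deterministic
    perturbations guard against bad starts.
    """
    x, y = _xy(eic)
    if not 1 <= n <= 4:
        raise ParameterError("gaussian sum order n must be in 1..4")
    if x.size < 3 * n + 1:
        raise ParameterError(f"need at least {3 * n + 1} points for order {n}")
    cid = eic.compound_id if isinstance(eic, EIC) else ""

    if _is_flat(y) and abs(float(np.mean(y))) <= 1e-12 * max(1.0, float(np.max(np.abs(y)))):
        params = np.tile([0.0, float(x.mean()), float(np.ptp(x) or 1.0)], n)
        return FitResult("gauss", n, params, np.nan, np.nan, 0.0, x, np.zeros_like(y),
                         degenerate=True, compound_id=cid)

    span = float(x[-1] - x[0]) or 1.0
    smooth = boxcar_smooth(y, min(21, (y.size // 2) * 2 - 1) if y.size > 42 else 3)
    peaks, props = find_peaks(smooth, height=0.0)
    order = np.argsort(props["peak_heights"])[::-1] if peaks.size else np.array([], int)
    centers = list(x[peaks[order[:n]]])
    # pad with evenly spread quantile positions
    k = 0
    while len(centers) < n:
        centers.append(float(x[0] + span * (k + 1) / (n + 1)))
        k += 1
    amp0 = max(float(smooth.max()), 1e-9)
    x0 = []
    for b in sorted(centers):
        x0 += [amp0, b, span / (2.0 * n)]
    x0 = np.asarray(x0)

    lo = np.tile([0.0, x[0] - span, 1e-6 * span], n)
    hi = np.tile([3.0 * max(amp0, float(y.max())), x[-1] + span, 3.0 * span], n)

    def resid(p):
        return _gauss_eval(p, x) - y

    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(restarts + 1):
        start = x0 if attempt == 0 else np.clip(
            x0 * (1.0 + 0.25 * rng.standard_normal(x0.size)), lo + 1e-12, hi - 1e-12
        )
        try:
            sol = least_squares(resid, start, bounds=(lo, hi),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost <= 1e-20 * max(1.0, float(y @ y)):
            break
    if best is None:
        raise FitError(f"gaussian-sum fit failed for order {n}")
    r2, adj, rmse = _gof(y, best.fun, x0.size)
    return FitResult("gauss", n, best.x, r2, adj, rmse, x, _gauss_eval(best.x, x),
                     degenerate=bool(np.isnan(r2)), compound_id=cid)


def _fourier_linear(x, y, w, n):
    """Exact linear coefficients given the angular frequency w."""
    cols = [np.ones_like(x)]
    for i in range(1, n + 1):
        cols += [np.cos(i * w * x), np.sin(i * w * x)]
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = design @ coef - y
    return coef, float(resid @ resid)


def fit_fourier(eic, n: int, seed: int = 1234) -> FitResult:
    """Fourier-series fit by variable projection over the base frequency.

    `w` is initialised from the dominant non-zero frequency of the
    detrended signal, refined by bounded scalar minimisation, and the
    linear coefficients are solved exactly at each candidate; a final
    joint nonlinear polish tightens everything.
    """
    x, y = _xy(eic)
    if not 1 <= n <= 3:
        raise ParameterError("fourier order n must be in 1..3")
    if x.size < 2 * n + 3:
        raise ParameterError(f"need at least {2 * n + 3} points for order {n}")
    cid = eic.compound_id if isinstance(eic, EIC) else ""
    span = float(x[-1] - x[0]) or 1.0

    if _is_flat(y):
        params = np.concatenate([[float(y.mean()), 2 * np.pi / span], np.zeros(2 * n)])
        return FitResult("fourier", n, params, np.nan, np.nan, 0.0, x, np.full_like(y, y.mean()),
                         degenerate=True, compound_id=cid)

    # dominant non-zero frequency of the detrended, evenly resampled signal
    xi = np.linspace(x[0], x[-1], x.size)
    yi = np.interp(xi, x, y)
    trend = np.polyval(np.polyfit(xi, yi, 1), xi)
    spec = np.abs(np.fft.rfft(yi - trend))
    freqs = np.fft.rfftfreq(xi.size, d=(xi[1] - xi[0]))
    k = int(np.argmax(spec[1:]) + 1) if spec.size > 1 else 1
    w_fft = 2.0 * np.pi * freqs[k]

    candidates = {w_fft} | {2.0 * np.pi * f / span for f in (0.25, 0.5, 1.0, 1.5, 2.0)}
    scored = []
    for w in candidates:
        if w <= 0:
            continue
        _, sse = _fourier_linear(x, y, w, n)
        scored.append((sse, w))
    scored.sort()
    w_best = scored[0][1]
    res = minimize_scalar(
        lambda w: _fourier_linear(x, y, w, n)[1] if w > 0 else np.inf,
        bounds=(0.3 * w_best, 3.0 * w_best), method="bounded",
        options={"xatol": 1e-12 * w_best},
    )
    if res.success and res.fun <= scored[0][0]:
        w_best = float(res.x)
    coef, _ = _fourier_linear(x, y, w_best, n)
    p0 = np.concatenate([[coef[0], w_best], coef[1:]])

    def resid(p):
        return _fourier_eval(p, x) - y

    lo = np.full(p0.size, -np.inf); lo[1] = 1e-12
    sol = least_squares(resid, p0, bounds=(lo, np.full(p0.size, np.inf)),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)
    r2, adj, rmse = _gof(y, sol.fun, p0.size)
    return FitResult("fourier", n, sol.x, r2, adj, rmse, x, _fourier_eval(sol.x, x),
                     degenerate=bool(np.isnan(r2)), compound_id=cid)


def select_model(fits: list[FitResult]) -> FitResult:
    """Highest adjusted R²; ties (<1e−6) broken by fewer parameters.

    The result does not depend on the order in which fits are supplied.
    """
    usable = [f for f in fits if f is not None and not f.degenerate and np.isfinite(f.adj_r2)]
    if not usable:
        degenerate = [f for f in fits if f is not None]
        if degenerate:
            # all-degenerate (e.g. constant) input: best residual, then parsimony
            return min(degenerate, key=lambda f: (f.rmse, f.n_params, f.model, f.n))
        raise FitError("no successful fits to select from")
    best_adj = max(f.adj_r2 for f in usable)
    tied = [f for f in usable if best_adj - f.adj_r2 < 1e-6]
    return min(tied, key=lambda f: (f.n_params, f.model, f.n))


def percent_change(reference_value: float, final_value: float) -> float:
    """Signed percent change from a positive reference to a final value."""
    if not np.isfinite(reference_value) or reference_value <= 0:
        raise ParameterError(f"reference must be > 0, got {reference_value}")
    return 100.0 * (final_value - reference_value) / reference_value


@dataclass
class KineticSummary:
    """Curve landmarks over an evaluation window."""

    compound_id: str
    window: tuple[float, float]
    initial: float
    peak_value: float
    peak_time: float
    final: float
    pct_change: float
    trend: Trend
    plateau: tuple[float, float] | None
    reliable: bool = True


def find_plateau(t: np.ndarray, v: np.ndarray, delta: float = 0.10,
                 s_max: float = 1e-3) -> tuple[float, float] | None:
    """Maximal interval around the curve maximum where the curve stays within
    a (1−delta) band of the max and the relative slope stays below s_max
    (per minute)."""
    vmax = float(v.max())
    if vmax <= 0:
        return None
    slope = np.gradient(v, t) / np.maximum(v, 1e-12 * vmax)
    ok = (v >= (1.0 - delta) * vmax) & (np.abs(slope) <= s_max)
    i_peak = int(np.argmax(v))
    if not ok[i_peak]:
        # numerical gradient at a narrow peak can miss zero; search nearby
        near = np.where(ok)[0]
        if near.size == 0:
            return None
        i_peak = int(near[np.argmin(np.abs(near - i_peak))])
    lo = i_peak
    while lo > 0 and ok[lo - 1]:
        lo -= 1
    hi = i_peak
    while hi < ok.size - 1 and ok[hi + 1]:
        hi += 1
    return float(t[lo]), float(t[hi])


def summarize_kinetics(fit: FitResult, window: tuple[float, float],
                       delta: float = 0.10, s_max: float = 1e-3,
                       grid_dt: float = 0.2) -> KineticSummary:
    """Read initial/peak/final values and classify the trend of a fitted curve.

    Trend rules: an interior peak exceeding both ends by >15 % → BIPHASIC;
    |percent change| < 10 % otherwise → STABLE; else the sign of the change.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ParameterError("window end must exceed start")
    t = np.arange(t0, t1 + 1e-9, grid_dt)
    v = fit.predict(t)
    initial, final = float(v[0]), float(v[-1])
    i_peak = int(np.argmax(v))
    peak_value, peak_time = float(v[i_peak]), float(t[i_peak])
    reliable = not fit.degenerate and initial > 0
    pct = percent_change(initial, final) if initial > 0 else np.nan

    interior = grid_dt < (peak_time - t0) and grid_dt < (t1 - peak_time)
    if interior and peak_value > 1.15 * max(initial, final):
        trend = Trend.BIPHASIC
    elif np.isfinite(pct) and abs(pct) < 10.0:
        trend = Trend.STABLE
    elif np.isfinite(pct):
        trend = Trend.RISING if pct > 0 else Trend.DECLINING
    else:
        trend = Trend.STABLE
        reliable = False
    plateau = find_plateau(t, v, delta=delta, s_max=s_max)
    return KineticSummary(fit.compound_id, (t0, t1), initial, peak_value,
                          peak_time, final, pct, trend, plateau, reliable)


@dataclass
class ComparisonResult:
    """Single- vs co-decoction comparison for one compound.

    `peak_ratio` is co/single peak intensity; `rate_ratio` is the
    single/co ratio of |percent change| (how much faster the compound
    moves when the herb is decocted alone).
    """

    compound_id: str
    summary_single: KineticSummary
    summary_co: KineticSummary
    peak_ratio: float | None
    rate_ratio: float | None
    concordant: bool


def compare_modes(summary_single: KineticSummary,
                  summary_co: KineticSummary) -> ComparisonResult:
    if summary_single.compound_id != summary_co.compound_id:
        raise ParameterError("summaries refer to different compounds")
    peak_ratio = (
        summary_co.peak_value / summary_single.peak_value
        if summary_single.peak_value > 0 else None
    )
    rate_ratio = (
        abs(summary_single.pct_change) / abs(summary_co.pct_change)
        if np.isfinite(summary_co.pct_change) and abs(summary_co.pct_change) > 0
        and np.isfinite(summary_single.pct_change)
        else None
    )
    return ComparisonResult(
        summary_single.compound_id, summary_single, summary_co,
        peak_ratio, rate_ratio,
        concordant=summary_single.trend == summary_co.trend,
    )
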