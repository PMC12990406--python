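"""EIC extraction, boxcar denoising and downsampling.

Per-compound intensity time-series are reconstructed from the raw scan
stream as extracted-ion chromatograms (EICs): for each scan, all intensity
within ±tol of the compound's nominal m/z is summed.  The series is then
denoised with a centred boxcar moving average (default window 3 points,
shrinking symmetrically at the edges) and optionally block-averaged onto a
coarser grid before curve fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyStreamError, ParameterError
from .stream import ScanStream

__all__ = ["EIC", "SmoothingConfig", "extract_eic", "boxcar_smooth",
           "downsample", "replicate_mean"]


@dataclass
class SmoothingConfig:
    """Boxcar window; `points` must be odd so the window is centred."""

    points: int = 3
    edge_policy: str = "shrink"

    def __post_init__(self):
        if self.points < 1 or self.points % 2 == 0:
            raise ConfigurationError(f"boxcar points must be odd and >= 1, got {self.points}")
        if self.edge_policy != "shrink":
            raise ConfigurationError(f"unknown edge policy {self.edge_policy!r}")


@dataclass
class EIC:
    """Extracted-ion chromatogram for one compound."""

    compound_id: str
    mz_center: float
    tol: float
    times_min: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.tol <= 0:
            raise ParameterError("tol must be > 0")
        if self.times_min.shape != self.raw.shape:
            raise ParameterError("times and intensities must have equal length")
        if self.smoothed is not None:
            self.smoothed = np.asarray(self.smoothed, dtype=float)
            if self.smoothed.shape != self.raw.shape:
                raise ParameterError("smoothed length mismatch")

    @property
    def values(self) -> np.ndarray:
        """Best available signal: smoothed if present, else raw."""
        return self.raw if self.smoothed is None else self.smoothed

    def smooth(self, config: SmoothingConfig | None = None) -> "EIC":
        config = config or SmoothingConfig()
        self.smoothed = boxcar_smooth(self.raw, config)
        return self

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_min": self.times_min, "raw": self.raw,
             "smoothed": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, compound_id="", mz_center=0.0, tol=0.5) -> "EIC":
        df = pd.read_csv(path)
        return cls(compound_id, mz_center, tol, df["time_min"].to_numpy(),
                   df["raw"].to_numpy(),
                   df["smoothed"].to_numpy() if "smoothed" in df else None)


def extract_eic(stream: ScanStream, mz_center: float, tol: float = 0.5,
                compound_id: str = "") -> EIC:
    """Sum, per scan, all intensity with |m/z − mz_center| ≤ tol.

    Times are converted from the acquisition clock (seconds) to minutes.
    """
    if len(stream) == 0:
        raise EmptyStreamError("cannot extract an EIC from an empty stream")
    if tol <= 0:
        raise ParameterError("tol must be > 0")
    mask = np.abs(stream.mz - mz_center) <= tol
    raw = stream.intensities[:, mask].sum(axis=1)
    return EIC(compound_id, mz_center, tol, stream.times_s / 60.0, raw)


def boxcar_smooth(values, config: SmoothingConfig | int | None = None) -> np.ndarray:
    """Centred moving average with symmetrically shrinking edge windows.

    At index i the half-width is min(half, i, n−1−i), so the first and last
    points are returned unchanged and the output never overshoots the data.
    """
    if isinstance(config, int):
        config = SmoothingConfig(points=config)
    config = config or SmoothingConfig()
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 1:
        raise ParameterError("values must be a non-empty 1-D array")
    half = (config.points - 1) // 2
    if half == 0:
        return y.copy()
    n = y.size
    # full-window moving average via cumulative sums, then fix the edges
    out = np.empty(n)
    c = np.concatenate([[0.0], np.cumsum(y)])
    for i in range(min(half, n)):
        h = min(i, n - 1 - i)
        out[i] = y[i - h:i + h + 1].mean()
        out[n - 1 - i] = y[n - 1 - i - h:n - i + h].mean()
    if n > 2 * half:
        idx = np.arange(half, n - half)
        out[idx] = (c[idx + half + 1] - c[idx - half]) / (2 * half + 1)
    return out


def downsample(eic: EIC, target_dt_min: float) -> EIC:
    """Block-average an EIC onto a coarser grid (timestamps at block centres)."""
    if eic.times_min.size < 2:
        raise ParameterError("need at least two points to downsample")
    native_dt = float(np.median(np.diff(eic.times_min)))
    m = int(round(target_dt_min / native_dt))
    if m < 2 or target_dt_min <= native_dt:
        raise ParameterError(
            f"target spacing {target_dt_min} min must exceed native {native_dt:g} min"
        )
    n_blocks = eic.times_min.size // m
    if n_blocks == 0:
        raise ParameterError("target spacing longer than the whole series")

    def block(v):
        return v[: n_blocks * m].reshape(n_blocks, m).mean(axis=1)

    return EIC(
        eic.compound_id, eic.mz_center, eic.tol,
        block(eic.times_min), block(eic.raw),
        None if eic.smoothed is None else block(eic.smoothed),
    )


def replicate_mean(eics: list[EIC]) -> tuple[EIC, np.ndarray]:
    """Pointwise mean across replicate EICs; returns (mean EIC, pointwise SD).

    Replicates are processed independently upstream and must share a grid.
    """
    if not eics:
        raise ParameterError("no replicates given")
    t0 = eics[0].times_min
    for e in eics[1:]:
        if e.times_min.shape != t0.shape or not np.allclose(e.times_min, t0):
            raise ParameterError("replicate EICs must share a common time grid")
    stack = np.vstack([e.values for e in eics])
    mean = EIC(eics[0].compound_id, eics[0].mz_center, eics[0].tol,
               t0.copy(), stack.mean(axis=0))
    sd = stack.std(axis=0, ddof=1) if len(eics) > 1 else np.zeros_like(t0)
    return mean, sd
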