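"""Calibrated Zhenwu Decoction (ZWD) scenario builder.

Ground-truth concentration traces for every library compound, in either the
single-herb or the co-decoction system.  The kinetic parameters live in the
versioned file ``data/zwd_params.yaml`` (regenerated by
``scripts/calibrate_zwd.py``); they are calibrated once so that, after
response-factor scaling, each curve passes within 5 % of its reference
intensity anchors in ``data/zwd_anchors.yaml``.

Single- and co-decoction parameter sets differ only through the documented
``co_modifiers`` factors (plus, for aconine, a transient loss term active in
the co-decoction system only).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError
from .kinetics import (
    CascadeParams,
    ConcentrationTrace,
    System,
    simulate_biphasic_intermediate,
    simulate_cascade,
)
from .library import CompoundSpec, load_library

__all__ = [
    "load_zwd_params",
    "load_zwd_anchors",
    "build_compound_trace",
    "build_zwd_scenario",
    "default_grid",
    "write_trace_csv",
    "read_trace_csv",
]

_DATA = resources.files("dwatch") / "data"


def load_zwd_params(path=None) -> dict:
    """Calibrated per-compound kinetic parameters (concentration units)."""
    p = Path(_DATA / "zwd_params.yaml") if path is None else Path(path)
    return yaml.safe_load(p.read_text())["compounds"]


def load_zwd_anchors(path=None) -> dict:
    """Reference intensity anchors and printed summary numbers."""
    p = Path(_DATA / "zwd_anchors.yaml") if path is None else Path(path)
    return yaml.safe_load(p.read_text())


def default_grid(duration_min: float = 240.0, dt_min: float = 0.1) -> np.ndarray:
    """Ground-truth evaluation grid; fine enough that linear interpolation
    onto the 5 Hz scan clock is exact to well below rendering noise."""
    return np.arange(0.0, duration_min + 1e-9, dt_min)


def build_compound_trace(
    compound_id: str,
    entry: dict,
    system: System,
    grid: np.ndarray,
) -> ConcentrationTrace:
    """Simulate one compound's ground-truth trace from its parameter entry."""
    params = entry[system.value]
    species = entry["species"]
    stages = entry.get("source_stages")
    if stages:
        trace = simulate_biphasic_intermediate(
            params["k1"],
            params["k2"],
            params["M0"],
            grid,
            source_release_rate=params["k_d"],
            source_stages=stages,
            system=system,
            compound_id=compound_id,
        )
        return trace
    tloss = None
    if system == System.CO and entry.get("co_transient_loss"):
        tloss = tuple(entry["co_transient_loss"])
    cascade_kwargs = {k: v for k, v in params.items() if k != "species"}
    res = simulate_cascade(
        CascadeParams(**cascade_kwargs),
        grid,
        transient_loss=tloss,
        compound_ids=(compound_id, compound_id, compound_id),
    )
    try:
        return {"A": res.A, "B": res.B, "C": res.C}[species]
    except KeyError as exc:
        raise ConfigurationError(
            f"unknown monitored species {species!r} for {compound_id!r}"
        ) from exc


def build_zwd_scenario(
    system: System | str,
    seed: int = 0,
    grid: np.ndarray | None = None,
    library: dict[str, CompoundSpec] | None = None,
    params: dict | None = None,
) -> dict[str, ConcentrationTrace]:
    """Ground-truth traces for the full ZWD compound library.

    The traces are deterministic: `seed` only labels the scenario for
    downstream stochastic stages (stream rendering) and never changes the
    noiseless ground truth.
    """
    system = System(system) if not isinstance(system, System) else system
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    library = load_library() if library is None else library
    params = load_zwd_params() if params is None else params

    missing = sorted(set(library) - set(params))
    if missing:
        raise ConfigurationError(f"no calibrated parameters for compounds: {missing}")

    return {
        cid: build_compound_trace(cid, params[cid], system, grid)
        for cid in library
    }


def write_trace_csv(trace: ConcentrationTrace, path) -> None:
    arr = np.column_stack([trace.times, trace.values])
    header = "time_min,value"
    np.savetxt(path, arr, delimiter=",", header=header, comments="", fmt="%.10g")


def read_trace_csv(path, compound_id: str = "", system: System = System.SINGLE) -> ConcentrationTrace:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    arr = np.atleast_2d(arr)
    return ConcentrationTrace(compound_id, system, arr[:, 0], arr[:, 1])
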