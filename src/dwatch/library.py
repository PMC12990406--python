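"""Compound library: the fixed set of monitored chemical species.

The library is a CSV with header ``id,name,herb,class,ion_mode,mz,
response_factor``.  ``mz`` is the nominal integer m/z of the monitored ion
(unit-resolution ion trap, one channel per compound) and ``response_factor``
converts concentration (arbitrary units) into detector counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError
from .kinetics import KineticClass

__all__ = ["CompoundSpec", "load_library", "save_library", "default_library_path"]

_COLUMNS = ["id", "name", "herb", "class", "ion_mode", "mz", "response_factor"]
_ION_MODES = {"pos", "neg"}


@dataclass(frozen=True)
class CompoundSpec:
    """One monitored species: identity, kinetic class and detection channel."""

    id: str
    name: str
    herb: str
    kinetic_class: KineticClass
    ion_mode: str
    mz: float
    response_factor: float

    def __post_init__(self):
        if self.ion_mode not in _ION_MODES:
            raise ConfigurationError(
                f"ion_mode must be one of {sorted(_ION_MODES)}, got {self.ion_mode!r}"
            )
        if not 100 <= self.mz <= 1500:
            raise ConfigurationError(f"mz {self.mz} outside the scan range [100, 1500]")
        if self.response_factor <= 0:
            raise ConfigurationError("response_factor must be > 0")


def default_library_path() -> Path:
    """Path of the packaged Zhenwu Decoction compound library."""
    return Path(resources.files("dwatch") / "data" / "zwd_library.csv")


def load_library(path=None) -> dict[str, CompoundSpec]:
    """Read a compound-library CSV into an ordered ``{id: CompoundSpec}`` map."""
    path = default_library_path() if path is None else Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"library {path} missing columns: {missing}")
    lib: dict[str, CompoundSpec] = {}
    for _, row in df.iterrows():
        try:
            kclass = KineticClass(row["class"])
        except ValueError as exc:
            raise ConfigurationError(
                f"unknown kinetic class {row['class']!r} for compound {row['id']!r}"
            ) from exc
        cid = str(row["id"])
        if cid in lib:
            raise ConfigurationError(f"duplicate compound id {cid!r}")
        lib[cid] = CompoundSpec(
            id=cid,
            name=str(row["name"]),
            herb=str(row["herb"]),
            kinetic_class=kclass,
            ion_mode=str(row["ion_mode"]),
            mz=float(row["mz"]),
            response_factor=float(row["response_factor"]),
        )
    return lib


def save_library(library: dict[str, CompoundSpec], path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": c.id,
                "name": c.name,
                "herb": c.herb,
                "class": c.kinetic_class.value,
                "ion_mode": c.ion_mode,
                "mz": c.mz,
                "response_factor": c.response_factor,
            }
            for c in library.values()
        ],
        columns=_COLUMNS,
    )
    df.to_csv(path, index=False)
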