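"""Full-scan MS stream: rendering, containers and file formats.

The acquisition contract mirrors a direct-infusion linear ion trap watching
a decoction flask: full scans over m/z 100–1500 at a fixed clock (5 Hz by
default, i.e. 72,000 scans per 240-minute run per ion mode), unit m/z
resolution, one channel per monitored compound.  Each compound deposits

    intensity = response_factor × concentration(t) × lognormal(CV)

at its nominal m/z, on top of an additive exponential baseline.

Canonical on-disk format is JSON-lines (one scan per line, bit-exact
round-trip); a minimal mzML writer is provided as a convenience and is read
back with pyteomics.
"""

from __future__ import annotations

import base64
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    CoverageError,
    ParameterError,
    StreamParseError,
)
from .kinetics import ConcentrationTrace
from .library import CompoundSpec

__all__ = ["Scan", "ScanStream", "AcquisitionConfig", "render_stream",
           "write_stream", "read_stream"]

MZ_MIN, MZ_MAX = 100.0, 1500.0


@dataclass
class Scan:
    """One full scan: time since acquisition start, polarity and the peak list."""

    time_s: float
    mode: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_s < 0:
            raise ParameterError("scan time must be >= 0")
        if self.mode not in ("pos", "neg"):
            raise ParameterError(f"mode must be 'pos' or 'neg', got {self.mode!r}")
        if self.mz.shape != self.intensity.shape:
            raise ParameterError("mz and intensity must have equal length")
        if self.mz.size:
            if np.any(np.diff(self.mz) <= 0):
                raise ParameterError("mz values must be strictly ascending")
            if self.mz[0] < MZ_MIN or self.mz[-1] > MZ_MAX:
                raise ParameterError(f"mz outside [{MZ_MIN}, {MZ_MAX}]")
        if np.any(self.intensity < 0):
            raise ParameterError("intensities must be non-negative")


@dataclass
class ScanStream:
    """Ordered scans of one ion mode sharing a common m/z channel grid."""

    mode: str
    times_s: np.ndarray
    mz: np.ndarray
    intensities: np.ndarray  # shape (n_scans, n_channels)

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.times_s.size, self.mz.size):
            raise ParameterError("intensity matrix shape mismatch")
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise ParameterError("scan times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size

    def __iter__(self):
        for i in range(len(self)):
            yield self.scan(i)

    def scan(self, i: int) -> Scan:
        return Scan(float(self.times_s[i]), self.mode, self.mz, self.intensities[i])

    @classmethod
    def from_scans(cls, scans: list[Scan], mode: str | None = None) -> "ScanStream":
        if not scans:
            return cls(mode or "pos", np.empty(0), np.empty(0), np.empty((0, 0)))
        mode = scans[0].mode if mode is None else mode
        for s in scans:
            if s.mode != mode:
                raise StreamParseError(f"mode mismatch: expected {mode!r}, got {s.mode!r}")
            if s.mz.shape != scans[0].mz.shape or not np.array_equal(s.mz, scans[0].mz):
                raise StreamParseError("scans do not share a common m/z channel grid")
        return cls(
            mode,
            np.array([s.time_s for s in scans]),
            scans[0].mz.copy(),
            np.vstack([s.intensity for s in scans]),
        )


@dataclass
class AcquisitionConfig:
    """Acquisition contract of the monitoring device.

    The 5 Hz default scan rate follows from ~72,000 intensity values per
    compound over a 240-minute run (300 scans/min).  Noise is multiplicative
    lognormal with coefficient of variation `noise_cv` plus an additive
    exponential baseline of mean `baseline_level` per channel.
    """

    mode: str = "pos"
    scan_rate_hz: float = 5.0
    duration_min: float = 240.0
    noise_cv: float = 0.05
    baseline_level: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("pos", "neg"):
            raise ConfigurationError("mode must be 'pos' or 'neg'")
        if self.scan_rate_hz <= 0 or self.duration_min <= 0:
            raise ConfigurationError("scan_rate_hz and duration_min must be > 0")
        if self.noise_cv < 0 or self.baseline_level < 0:
            raise ConfigurationError("noise_cv and baseline_level must be >= 0")

    @property
    def n_scans(self) -> int:
        return int(np.floor(self.scan_rate_hz * self.duration_min * 60.0))

    def scan_times_s(self) -> np.ndarray:
        return np.arange(self.n_scans) / self.scan_rate_hz


def render_stream(
    traces: dict[str, ConcentrationTrace],
    library: dict[str, CompoundSpec],
    config: AcquisitionConfig,
) -> ScanStream:
    """Render ground-truth traces into a noisy full-scan stream.

    Compounds whose ion mode matches ``config.mode`` each occupy their
    nominal m/z channel.  Reproducible for a fixed ``config.seed``;
    different seeds change only the noise, never the deposited signal.
    """
    active = [c for cid, c in library.items() if c.ion_mode == config.mode and cid in traces]
    times_s = config.scan_times_s()
    times_min = times_s / 60.0
    for comp in active:
        tr = traces[comp.id]
        if tr.times[0] > times_min[0] + 1e-12 or tr.times[-1] < times_min[-1] - 1e-12:
            raise CoverageError(
                f"trace for {comp.id!r} covers [{tr.times[0]:g}, {tr.times[-1]:g}] min "
                f"but acquisition needs [{times_min[0]:g}, {times_min[-1]:g}]"
            )

    mz = np.array(sorted({comp.mz for comp in active}), dtype=float)
    chan = {v: i for i, v in enumerate(mz)}
    rng = np.random.default_rng(config.seed)

    signal = np.zeros((times_s.size, mz.size))
    for comp in active:
        clean = comp.response_factor * traces[comp.id].at(times_min)
        if config.noise_cv > 0:
            sigma = np.sqrt(np.log1p(config.noise_cv**2))
            noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=clean.shape)
            clean = clean * noise
        signal[:, chan[comp.mz]] += clean
    if config.baseline_level > 0:
        signal += rng.exponential(config.baseline_level, size=signal.shape)
    return ScanStream(config.mode, times_s, mz, signal)


# ---------------------------------------------------------------------------
# JSON-lines dialect: {"t_s": ..., "mode": "pos", "mz": [...], "intensity": [...]}

def _write_jsonl(stream: ScanStream, path: Path) -> None:
    with open(path, "w") as fh:
        for scan in stream:
            fh.write(
                json.dumps(
                    {
                        "t_s": scan.time_s,
                        "mode": scan.mode,
                        "mz": scan.mz.tolist(),
                        "intensity": scan.intensity.tolist(),
                    }
                )
            )
            fh.write("\n")


def _read_jsonl(path: Path) -> ScanStream:
    scans = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise StreamParseError(f"invalid JSON ({exc.msg})", line=lineno) from exc
            try:
                scans.append(
                    Scan(float(obj["t_s"]), obj["mode"],
                         np.asarray(obj["mz"], float), np.asarray(obj["intensity"], float))
                )
            except (KeyError, TypeError, ParameterError) as exc:
                raise StreamParseError(str(exc), line=lineno) from exc
    return ScanStream.from_scans(scans)


# ---------------------------------------------------------------------------
# Minimal mzML writer (32-bit float, no compression); read via pyteomics.

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64_f32(arr: np.ndarray) -> str:
    return base64.b64encode(np.asarray(arr, dtype="<f4").tobytes()).decode("ascii")


def _write_mzml(stream: ScanStream, path: Path) -> None:
    polarity = (
        '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>'
        if stream.mode == "pos"
        else '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>'
    )
    with open(path, "w") as fh:
        fh.write(_MZML_HEADER.format(count=len(stream)))
        for i, scan in enumerate(stream):
            mz64 = _b64_f32(scan.mz)
            it64 = _b64_f32(scan.intensity)
            fh.write(f"""      <spectrum index="{i}" id="scan={i}" defaultArrayLength="{scan.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
        {polarity}
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{scan.time_s}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz64)}">
            <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(it64)}">
            <cvParam cvRef="MS" accession="MS:1000521" name="32-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{it64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
        fh.write(_MZML_FOOTER)


def _read_mzml(path: Path) -> ScanStream:
    """Minimal mzML reader for the subset this package writes
    (uncompressed 32-bit float arrays, one scan per spectrum)."""
    import xml.etree.ElementTree as ET

    ns = "{http://psi.hupo.org/ms/mzml}"
    scans = []
    for _, spectrum in ET.iterparse(str(path)):
        if spectrum.tag != f"{ns}spectrum":
            continue
        mode, t_s, mz_arr, it_arr = None, None, None, None
        for cv in spectrum.iter(f"{ns}cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000130":
                mode = "pos"
            elif acc == "MS:1000129":
                mode = "neg"
            elif acc == "MS:1000016":
                t_s = float(cv.get("value"))
        for bda in spectrum.iter(f"{ns}binaryDataArray"):
            accs = {cv.get("accession") for cv in bda.iter(f"{ns}cvParam")}
            raw = bda.find(f"{ns}binary").text or ""
            data = np.frombuffer(base64.b64decode(raw), dtype="<f4").astype(float)
            if "MS:1000514" in accs:
                mz_arr = data
            elif "MS:1000515" in accs:
                it_arr = data
        if mode is None or t_s is None or mz_arr is None or it_arr is None:
            raise StreamParseError(f"incomplete spectrum in {path}")
        scans.append(Scan(t_s, mode, mz_arr, it_arr))
        spectrum.clear()
    return ScanStream.from_scans(scans)


def write_stream(stream: ScanStream, path, format: str | None = None) -> None:
    """Write a stream as `jsonl` (canonical, exact) or `mzml` (float32)."""
    path = Path(path)
    format = format or ("mzml" if path.suffix.lower() == ".mzml" else "jsonl")
    if format == "jsonl":
        _write_jsonl(stream, path)
    elif format == "mzml":
        _write_mzml(stream, path)
    else:
        raise ConfigurationError(f"unknown stream format {format!r}")


def read_stream(path, format: str | None = None) -> ScanStream:
    path = Path(path)
    format = format or ("mzml" if path.suffix.lower() == ".mzml" else "jsonl")
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "mzml":
        return _read_mzml(path)
    raise ConfigurationError(f"unknown stream format {format!r}")
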