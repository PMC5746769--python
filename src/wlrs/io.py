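"""Plain-text readers/writers and the flat key-value run configuration.

All on-disk formats are delimited text with a one-line column header;
comment lines starting with ``#`` carry provenance (package version, seed,
config hash) and are ignored on read.  Spectra are
``wavelength_nm,value``, sensorgrams ``time_s,thickness_nm,converged``,
peak tracks ``time_s,lambda_max_nm``, calibrator tables
``concentration,response`` and scan profiles ``position_mm,signal``.

The run configuration is a flat ``key = value`` file with dotted section
names (``stack.layers``, ``fit.window``, ...).  Unknown keys are rejected
by name so typos fail loudly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import BindingParams
from .errors import ConfigError, SpectrumFormatError
from .fitting import FitProblem, Sensorgram
from .optics import LayerStack, OpticalLayer, Spectrum, WavelengthGrid

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_sensorgram",
    "write_sensorgram",
    "read_calibrators",
    "write_scan",
    "write_peak_track",
    "RunConfig",
    "load_config",
]


def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in provenance.items())


def write_spectrum(spec: Spectrum, path: str | Path, provenance: dict | None = None) -> None:
    """Write a spectrum as ``wavelength_nm,value`` CSV (lossless repr)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("wavelength_nm,value\n")
        for wl, v in zip(spec.wavelengths, spec.values):
            fh.write(f"{float(wl)!r},{float(v)!r}\n")


def read_spectrum(path: str | Path, kind: str = "reflectance") -> Spectrum:
    """Read a two-column spectrum file; full-precision round trip.

    Malformed rows are reported with their (1-based) line number;
    non-increasing wavelengths are a format error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pandas parse failure
        raise SpectrumFormatError(f"cannot parse {path}: {exc}") from exc
    expected = ["wavelength_nm", "value"]
    if list(df.columns) != expected:
        raise SpectrumFormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    wl = pd.to_numeric(df["wavelength_nm"], errors="coerce").to_numpy()
    vals = pd.to_numeric(df["value"], errors="coerce").to_numpy()
    bad = ~(np.isfinite(wl) & np.isfinite(vals))
    if bad.any():
        # reconstruct the physical line number: header + comments precede data
        data_row = int(np.flatnonzero(bad)[0])
        n_comments = 0
        with path.open() as fh:
            for line in fh:
                if line.startswith("#"):
                    n_comments += 1
                else:
                    break
        raise SpectrumFormatError(
            f"{path}: non-numeric or missing value", line=n_comments + 2 + data_row
        )
    if wl.size > 1 and np.any(np.diff(wl) <= 0):
        raise SpectrumFormatError(f"{path}: wavelengths must be strictly increasing")
    return Spectrum(grid=WavelengthGrid(wl), values=vals, kind=kind)


def write_sensorgram(sg: Sensorgram, path: str | Path, provenance: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("time_s,thickness_nm,converged\n")
        for t, d, c in zip(sg.times, sg.thickness, sg.converged):
            fh.write(f"{float(t)!r},{float(d)!r},{int(c)}\n")


def read_sensorgram(path: str | Path) -> Sensorgram:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cols = ["time_s", "thickness_nm", "converged"]
    if list(df.columns) != cols:
        raise SpectrumFormatError(f"{path}: expected columns {cols}, found {list(df.columns)}")
    return Sensorgram(
        times=df["time_s"].to_numpy(float),
        thickness=df["thickness_nm"].to_numpy(float),
        converged=df["converged"].to_numpy(bool),
    )


def read_calibrators(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a ``concentration,response`` calibrator table."""
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    cols = ["concentration", "response"]
    if list(df.columns) != cols:
        raise SpectrumFormatError(f"{path}: expected columns {cols}, found {list(df.columns)}")
    return df["concentration"].to_numpy(float), df["response"].to_numpy(float)


def write_scan(
    positions: np.ndarray, signals: np.ndarray, path: str | Path, provenance: dict | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("position_mm,signal\n")
        for x, s in zip(positions, signals):
            fh.write(f"{float(x)!r},{float(s)!r}\n")


def write_peak_track(track, path: str | Path, provenance: dict | None = None) -> None:
    """Write a λ_max track as ``time_s,lambda_max_nm`` CSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_provenance_lines(provenance))
        fh.write("time_s,lambda_max_nm\n")
        for t, lam in zip(track.times, track.lambda_max):
            fh.write(f"{float(t)!r},{float(lam)!r}\n")


def write_series(
    series: list[tuple[float, Spectrum]],
    directory: str | Path,
    provenance: dict | None = None,
) -> None:
    """Write a timestamped spectrum series as one CSV per frame.

    The frame time is stored in a ``# time_s=...`` header comment so file
    names need not encode it.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, (t, spec) in enumerate(series):
        prov = {"time_s": repr(float(t))}
        if provenance:
            prov.update(provenance)
        write_spectrum(spec, directory / f"frame_{i:05d}.csv", provenance=prov)


def read_series(directory: str | Path) -> list[tuple[float, Spectrum]]:
    """Read every ``*.csv`` frame in a directory, ordered by its time stamp."""
    directory = Path(directory)
    frames: list[tuple[float, Spectrum]] = []
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise SpectrumFormatError(f"no spectrum files (*.csv) found in {directory}")
    for p in paths:
        t = None
        with p.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# time_s="):
                    t = float(line.partition("=")[2])
        if t is None:
            raise SpectrumFormatError(f"{p}: missing '# time_s=' header comment")
        frames.append((t, read_spectrum(p)))
    frames.sort(key=lambda item: item[0])
    return frames


# --------------------------------------------------------------------------
# Run configuration

_KNOWN_KEYS = {
    "stack.ambient_index",
    "stack.substrate_index",
    "stack.layers",
    "grid.start",
    "grid.stop",
    "grid.points",
    "fit.window",
    "fit.free",
    "fit.max_adlayer",
    "noise.sd",
    "kinetics.k_on",
    "kinetics.k_off",
    "kinetics.conc",
    "kinetics.d_max",
    "kinetics.duration",
    "kinetics.interval",
    "scan.band_width",
    "scan.band_pitch",
    "scan.n_bands",
    "scan.spot_fwhm",
    "scan.step",
    "scan.responses",
    "resolve.replicates",
    "seed",
}

_DEFAULTS = {
    "stack.ambient_index": "1.0",
    "stack.substrate_index": "4.0",
    "stack.layers": "SiO2:1.46:1000",
    "grid.start": "450",
    "grid.stop": "800",
    "grid.points": "512",
    "noise.sd": "0.002",
    "seed": "0",
    "resolve.replicates": "200",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration: stack, grid, fit, generator settings."""

    raw: dict[str, str]
    source_text: str = ""

    @property
    def sha256(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:12]

    def get(self, key: str, default: str | None = None) -> str | None:
        if key in self.raw:
            return self.raw[key]
        if key in _DEFAULTS:
            return _DEFAULTS[key]
        return default

    def get_float(self, key: str, default: float | None = None) -> float:
        v = self.get(key)
        if v is None:
            if default is None:
                raise ConfigError(f"missing required key {key!r}")
            return default
        try:
            return float(v)
        except ValueError as exc:
            raise ConfigError(f"key {key!r}: not a number: {v!r}") from exc

    def get_int(self, key: str, default: int | None = None) -> int:
        return int(self.get_float(key, default))

    @property
    def seed(self) -> int:
        return self.get_int("seed")

    def stack(self) -> LayerStack:
        layers = []
        spec = self.get("stack.layers")
        for item in spec.split(","):
            item = item.strip()
            if not item:
                continue
            parts = item.split(":")
            if len(parts) != 3:
                raise ConfigError(
                    f"stack.layers entry {item!r}: expected name:index:thickness_nm"
                )
            name, n_s, d_s = (p.strip() for p in parts)
            try:
                layers.append(OpticalLayer(name=name, refractive_index=float(n_s), thickness=float(d_s)))
            except ValueError as exc:
                raise ConfigError(f"stack.layers entry {item!r}: {exc}") from exc
        return LayerStack(
            ambient_index=self.get_float("stack.ambient_index"),
            layers=tuple(layers),
            substrate_index=self.get_float("stack.substrate_index"),
        )

    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(
            np.linspace(
                self.get_float("grid.start"),
                self.get_float("grid.stop"),
                self.get_int("grid.points"),
            )
        )

    def fit_window(self) -> tuple[float, float] | None:
        w = self.get("fit.window")
        if w is None:
            return None
        parts = w.split(",")
        if len(parts) != 2:
            raise ConfigError(f"fit.window {w!r}: expected 'lo,hi' in nm")
        lo, hi = (float(p) for p in parts)
        if hi <= lo:
            raise ConfigError(f"fit.window {w!r}: upper edge must exceed lower edge")
        return (lo, hi)

    def fit_problem(self) -> FitProblem:
        stack = self.stack()
        free = self.get("fit.free")
        if free is None:
            raise ConfigError("missing required key 'fit.free'")
        names = tuple(p.strip() for p in free.split(",") if p.strip())
        bounds = {}
        max_ad = self.get("fit.max_adlayer")
        if max_ad is not None:
            for name in names:
                if not name.startswith("index:") and stack.layer(name).thickness < 50:
                    bounds[name] = (0.0, float(max_ad))
        return FitProblem(
            model_stack=stack,
            free_parameters=names,
            bounds=bounds,
            spectral_window=self.fit_window(),
        )

    def binding_params(self) -> BindingParams:
        return BindingParams(
            k_on=self.get_float("kinetics.k_on"),
            k_off=self.get_float("kinetics.k_off"),
            analyte_conc=self.get_float("kinetics.conc"),
            d_max=self.get_float("kinetics.d_max"),
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a flat ``key = value`` configuration file.

    Blank lines and ``#`` comments are ignored; unknown keys raise
    :class:`ConfigError` naming the offender.
    """
    path = Path(path)
    text = path.read_text()
    raw: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {stripped!r}")
        key, _, value = stripped.partition("=")
        key = key.strip()
        if key not in _KNOWN_KEYS:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        if key in raw:
            raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
        raw[key] = value.strip()
    return RunConfig(raw=raw, source_text=text)
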