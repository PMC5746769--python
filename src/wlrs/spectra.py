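"""Raw-spectrum normalization, fringe analysis and peak-shift conversion.

A measurement session acquires three raw spectra: the signal S(λ) from the
sensing chip, a reference REF(λ) from a plain Si chip, and a dark spectrum
D(λ) with the source off.  The absolute reflectance is

    R(λ) = (S(λ) − D(λ)) / (REF(λ) − D(λ)).

Binding of biomolecules increases the optical path through the stack and
shifts the interference fringes of R(λ) to longer wavelengths.  Two readout
strategies are supported: full-spectrum fitting (module :mod:`wlrs.fitting`)
and tracking of the main interference extremum λ_max in a short spectral
window, whose shift Δλ converts to an adlayer thickness change through the
linearised relation Δd₁ = k · (Δλ/λ) · d₂ with k ≈ 2.06 for the standard
protein/SiO₂-photoresist/Si stack.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import (
    DegenerateReferenceError,
    GridMismatchError,
    InvalidInputError,
    TrackingError,
)
from .optics import Spectrum, WavelengthGrid

__all__ = [
    "RawSpectrumSet",
    "PeakTrack",
    "ShiftConversionParams",
    "Extremum",
    "normalize_reflectance",
    "locate_extrema",
    "count_fringes",
    "track_peak",
    "shift_to_thickness",
]

#: Default prominence filter, as a fraction of the local amplitude range.
DEFAULT_PROMINENCE = 0.02

#: Default half-width of the λ_max tracking window, nm.
DEFAULT_WINDOW_HALF_WIDTH = 40.0


@dataclass(frozen=True)
class RawSpectrumSet:
    """Signal, reference and dark spectra sharing one wavelength grid."""

    signal: Spectrum
    reference: Spectrum
    dark: Spectrum

    def __post_init__(self) -> None:
        g = self.signal.wavelengths
        for other in (self.reference, self.dark):
            if other.wavelengths.shape != g.shape or not np.array_equal(other.wavelengths, g):
                raise GridMismatchError(
                    "signal, reference and dark spectra must share one wavelength grid"
                )


@dataclass(frozen=True)
class Extremum:
    """One located interference extremum (sub-grid resolution)."""

    wavelength: float
    value: float
    kind: str  # "min" | "max"


@dataclass(frozen=True)
class PeakTrack:
    """Time series of the tracked extremum wavelength λ_max."""

    times: np.ndarray
    lambda_max: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        lm = np.asarray(self.lambda_max, dtype=float)
        if t.shape != lm.shape or t.ndim != 1:
            raise InvalidInputError("times and lambda_max must be 1-D and equal length")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InvalidInputError("times must be strictly increasing")
        t.setflags(write=False)
        lm.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "lambda_max", lm)

    @property
    def shifts(self) -> np.ndarray:
        """Δλ relative to the first frame."""
        return self.lambda_max - self.lambda_max[0]


@dataclass(frozen=True)
class ShiftConversionParams:
    """Constants of the linearised peak-shift → thickness conversion.

    ``factor`` is the dimensionless calibration constant (2.06 for the
    standard stack with protein n = 1.46, SiO₂-photoresist n = 1.40, Si
    n = 4.00); ``d2`` the composite transducer-layer thickness in nm;
    ``lambda_ref`` the tracked peak wavelength before binding.
    """

    factor: float = 2.06
    d2: float = 1040.0
    lambda_ref: float = 600.0

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise InvalidInputError(f"factor must be > 0, got {self.factor}")
        if self.d2 <= 0:
            raise InvalidInputError(f"d2 must be > 0, got {self.d2}")
        if self.lambda_ref <= 0:
            raise InvalidInputError(f"lambda_ref must be > 0, got {self.lambda_ref}")


def normalize_reflectance(raw: RawSpectrumSet) -> Spectrum:
    """Absolute reflectance R(λ) = (S − D)/(REF − D), pointwise.

    Raises :class:`DegenerateReferenceError` naming the first wavelength at
    which the denominator is non-positive.
    """
    denom = raw.reference.values - raw.dark.values
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        raise DegenerateReferenceError(float(raw.signal.wavelengths[bad[0]]))
    values = (raw.signal.values - raw.dark.values) / denom
    return Spectrum(grid=raw.signal.grid, values=values, kind="reflectance")


def _quadratic_refine(wl: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex of the parabola through points i−1, i, i+1 (sub-grid position)."""
    x0, x1, x2 = wl[i - 1], wl[i], wl[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a == 0.0:  # flat triple — keep the grid point
        return float(x1), float(y1)
    xv = -b / (2 * a)
    c = y1 - a * x1**2 - b * x1
    return float(xv), float(a * xv**2 + b * xv + c)


def locate_extrema(
    spec: Spectrum,
    wavelength_range: tuple[float, float] | None = None,
    prominence: float = DEFAULT_PROMINENCE,
) -> list[Extremum]:
    """Interference minima and maxima in a wavelength range.

    Candidate extrema come from a local peak search with a prominence
    threshold of ``prominence`` × (local amplitude range), which rejects
    noise wiggles; positions are then refined to sub-grid resolution by a
    3-point quadratic interpolation through each extremum and its two
    neighbours.  Returned sorted by wavelength.
    """
    wl = spec.wavelengths
    y = spec.values
    if wavelength_range is not None:
        lo, hi = wavelength_range
        sel = (wl >= lo) & (wl <= hi)
        wl, y = wl[sel], y[sel]
    if wl.size < 3:
        raise InvalidInputError("need at least 3 grid points in the search range")

    amplitude = float(np.ptp(y))
    prom_abs = prominence * amplitude if amplitude > 0 else None
    out: list[Extremum] = []
    for sign, kind in ((1.0, "max"), (-1.0, "min")):
        idx, _ = find_peaks(sign * y, prominence=prom_abs)
        for i in idx:
            x_ref, y_ref = _quadratic_refine(wl, y, int(i))
            out.append(Extremum(wavelength=x_ref, value=y_ref, kind=kind))
    out.sort(key=lambda e: e.wavelength)
    return out


def count_fringes(
    spec: Spectrum,
    wavelength_range: tuple[float, float] = (450.0, 800.0),
    prominence: float = DEFAULT_PROMINENCE,
) -> int:
    """Number of interference fringes in a range.

    A fringe is operationalised as one reflectance minimum passing the
    prominence filter — the minimum is the feature the readout tracks.
    """
    extrema = locate_extrema(spec, wavelength_range, prominence)
    return sum(1 for e in extrema if e.kind == "min")


def track_peak(
    series: Sequence[tuple[float, Spectrum]],
    window: tuple[float, float],
    prominence: float = DEFAULT_PROMINENCE,
    half_width: float = DEFAULT_WINDOW_HALF_WIDTH,
) -> PeakTrack:
    """Follow the main interference extremum through a timestamped series.

    The first frame is searched in ``window``; each subsequent frame in a
    ±``half_width`` nm window re-centred on the previous λ_max, so the
    tracker follows slow drifts.  Each frame must contain exactly one
    extremum in its window, else :class:`TrackingError` carries the
    timestamp.
    """
    if len(series) == 0:
        raise InvalidInputError("empty spectrum series")
    times = []
    lambdas = []
    current_window = (float(window[0]), float(window[1]))
    for t, spec in series:
        found = locate_extrema(spec, current_window, prominence)
        if len(found) != 1:
            raise TrackingError(time_s=float(t), n_found=len(found))
        lam = found[0].wavelength
        times.append(float(t))
        lambdas.append(lam)
        current_window = (lam - half_width, lam + half_width)
    return PeakTrack(
        times=np.asarray(times), lambda_max=np.asarray(lambdas), window=window
    )


def shift_to_thickness(delta_lambda, params: ShiftConversionParams):
    """Adlayer thickness change Δd₁ = factor · (Δλ/λ_ref) · d₂, in nm.

    Exactly linear and homogeneous in Δλ; accepts scalars or arrays.
    """
    out = params.factor * (np.asarray(delta_lambda, dtype=float) / params.lambda_ref) * params.d2
    return float(out) if np.isscalar(delta_lambda) else out
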