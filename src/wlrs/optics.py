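"""Multilayer thin-film reflectance forward model at normal incidence.

The sensing chip is a stack of transparent dielectric films (SiO₂, Si₃N₄,
photoresist, a growing biomolecular adlayer) on a silicon substrate, probed
vertically with broadband light.  Partial beams reflected at each interface
interfere, producing a fringed reflectance spectrum; film growth shifts the
fringes.  This module computes that spectrum three ways:

* :func:`effective_reflectance_recursive` — the Abeles backward recursion,
  combining Fresnel interface coefficients and per-layer round-trip phases
  into one effective complex reflection coefficient, for any number of
  layers;
* :func:`reflectance_two_layer_closed` — the fully expanded closed form for
  the two-film case (ambient | film 1 | film 2 | substrate), the transducer
  geometry used throughout;
* :func:`simulate_spectrum` — the recursion evaluated over a wavelength
  grid, returning a :class:`Spectrum`.

Conventions: indices are real and dispersionless by default (a wavelength →
index callable is accepted for dispersion); the substrate is semi-infinite
(opaque Si, no backside reflection); reflectance is the squared magnitude of
the effective amplitude coefficient.
"""

from __future__ import annotations

import math
from collections.abc import Callable
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "OpticalLayer",
    "LayerStack",
    "WavelengthGrid",
    "EffectiveCoefficient",
    "Spectrum",
    "fresnel_amplitude",
    "phase_thickness",
    "effective_reflectance_recursive",
    "reflectance_two_layer_closed",
    "simulate_spectrum",
    "default_grid",
]

IndexLike = float | Callable[[np.ndarray], np.ndarray]


def _index_at(n: IndexLike, wavelengths: np.ndarray) -> np.ndarray:
    """Evaluate a constant or dispersive refractive index on a grid."""
    if callable(n):
        out = np.asarray(n(wavelengths), dtype=float)
        if out.shape != np.shape(wavelengths):
            out = np.broadcast_to(out, np.shape(wavelengths)).copy()
    else:
        out = np.full(np.shape(wavelengths), float(n))
    if np.any(out <= 0) or not np.all(np.isfinite(out)):
        raise InvalidInputError("refractive index must be finite and > 0")
    return out


@dataclass(frozen=True)
class OpticalLayer:
    """One transparent film: a name, a refractive index and a thickness.

    ``refractive_index`` may be a plain number or a callable mapping a
    wavelength array (nm) to an index array (Cauchy-type dispersion).
    ``thickness`` is in nanometres and must be finite and non-negative.
    """

    name: str
    refractive_index: IndexLike
    thickness: float

    def __post_init__(self) -> None:
        if not callable(self.refractive_index):
            n = float(self.refractive_index)
            if not math.isfinite(n) or n <= 0:
                raise InvalidInputError(
                    f"layer {self.name!r}: refractive index must be > 0, got {n}"
                )
        d = float(self.thickness)
        if not math.isfinite(d) or d < 0:
            raise InvalidInputError(
                f"layer {self.name!r}: thickness must be finite and >= 0, got {d}"
            )

    def with_thickness(self, thickness: float) -> "OpticalLayer":
        return replace(self, thickness=thickness)


@dataclass(frozen=True)
class LayerStack:
    """Ordered optical description: ambient on top, films, substrate below.

    The ambient is medium 0; interface *i* | *i*+1 sits between consecutive
    media.  An empty layer list describes a bare substrate.
    """

    ambient_index: float = 1.0
    layers: tuple[OpticalLayer, ...] = field(default_factory=tuple)
    substrate_index: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        for nm, val in (("ambient", self.ambient_index), ("substrate", self.substrate_index)):
            v = float(val)
            if not math.isfinite(v) or v <= 0:
                raise InvalidInputError(f"{nm} index must be finite and > 0, got {v}")

    @property
    def layer_names(self) -> tuple[str, ...]:
        return tuple(layer.name for layer in self.layers)

    def layer(self, name: str) -> OpticalLayer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise InvalidInputError(f"no layer named {name!r} in stack {self.layer_names}")

    def with_layer_thickness(self, name: str, thickness: float) -> "LayerStack":
        """Return a copy with the named layer's thickness replaced."""
        if name not in self.layer_names:
            raise InvalidInputError(f"no layer named {name!r} in stack {self.layer_names}")
        new = tuple(
            lyr.with_thickness(thickness) if lyr.name == name else lyr for lyr in self.layers
        )
        return replace(self, layers=new)

    def with_layer_index(self, name: str, refractive_index: float) -> "LayerStack":
        if name not in self.layer_names:
            raise InvalidInputError(f"no layer named {name!r} in stack {self.layer_names}")
        new = tuple(
            replace(lyr, refractive_index=refractive_index) if lyr.name == name else lyr
            for lyr in self.layers
        )
        return replace(self, layers=new)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength grid in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 1:
            raise InvalidInputError("wavelength grid must be a 1-D non-empty array")
        if np.any(wl <= 0) or not np.all(np.isfinite(wl)):
            raise InvalidInputError("wavelengths must be finite and > 0")
        if wl.size > 1 and np.any(np.diff(wl) <= 0):
            raise InvalidInputError("wavelengths must be strictly increasing")
        wl.setflags(write=False)
        object.__setattr__(self, "wavelengths", wl)

    def __len__(self) -> int:
        return int(self.wavelengths.size)


def default_grid(start: float = 450.0, stop: float = 800.0, points: int = 512) -> WavelengthGrid:
    """The platform's working visible range, 450–800 nm."""
    return WavelengthGrid(np.linspace(start, stop, points))


@dataclass(frozen=True)
class EffectiveCoefficient:
    """Polar form ρ·e^{iΔ} of the effective reflection coefficient."""

    amplitude: float
    phase: float

    @classmethod
    def from_complex(cls, r: complex) -> "EffectiveCoefficient":
        return cls(amplitude=abs(r), phase=float(np.angle(r)))


@dataclass(frozen=True)
class Spectrum:
    """Intensity per wavelength; ``kind`` tags the processing stage."""

    grid: WavelengthGrid
    values: np.ndarray
    kind: str = "reflectance"

    KINDS = ("raw", "reference", "dark", "reflectance")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise InvalidInputError(f"kind must be one of {self.KINDS}, got {self.kind!r}")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.grid),):
            raise InvalidInputError(
                f"values shape {vals.shape} does not match grid length {len(self.grid)}"
            )
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths


def fresnel_amplitude(n_i: float, n_j: float) -> float:
    """Normal-incidence Fresnel amplitude coefficient r = (nᵢ − nⱼ)/(nᵢ + nⱼ).

    Antisymmetric under media swap; zero for index-matched media.
    """
    n_i, n_j = float(n_i), float(n_j)
    if n_i <= 0 or n_j <= 0:
        raise InvalidInputError("refractive indices must be > 0")
    return (n_i - n_j) / (n_i + n_j)


def phase_thickness(layer: OpticalLayer, wavelength: float) -> float:
    """One-pass phase δ = 2π·n·d/λ accumulated crossing the layer once.

    The interference cosines carry 2δ (the round trip).
    """
    if wavelength <= 0:
        raise InvalidInputError("wavelength must be > 0")
    n = _index_at(layer.refractive_index, np.asarray(wavelength, dtype=float))
    return float(2.0 * np.pi * n * layer.thickness / wavelength)


def _stack_arrays(
    stack: LayerStack, wavelengths: np.ndarray
) -> tuple[list[np.ndarray], list[float]]:
    """Per-medium index arrays (ambient..substrate) and layer thicknesses."""
    indices = [_index_at(stack.ambient_index, wavelengths)]
    thicknesses: list[float] = []
    for lyr in stack.layers:
        indices.append(_index_at(lyr.refractive_index, wavelengths))
        thicknesses.append(float(lyr.thickness))
    indices.append(_index_at(stack.substrate_index, wavelengths))
    return indices, thicknesses


def _effective_r(stack: LayerStack, wavelengths: np.ndarray) -> np.ndarray:
    """Abeles backward recursion, vectorised over the wavelength axis.

    Start at the deepest interface with its bare Fresnel coefficient; fold
    each layer in from below via its round-trip phase factor e^{-2iδ}.
    """
    indices, thicknesses = _stack_arrays(stack, wavelengths)
    r_eff = ((indices[-2] - indices[-1]) / (indices[-2] + indices[-1])).astype(complex)
    for k in range(len(thicknesses) - 1, -1, -1):
        # layer k sits between interfaces k|k+1 (above) and k+1|k+2 (below)
        delta = 2.0 * np.pi * indices[k + 1] * thicknesses[k] / wavelengths
        phase = np.exp(-2j * delta)
        r_top = (indices[k] - indices[k + 1]) / (indices[k] + indices[k + 1])
        r_eff = (r_top + r_eff * phase) / (1.0 + r_top * r_eff * phase)
    return r_eff


def effective_reflectance_recursive(stack: LayerStack, wavelength: float) -> complex:
    """Effective complex reflection coefficient of the whole stack at one λ.

    Its squared magnitude is the reflectance.  Use :func:`simulate_spectrum`
    for whole-grid evaluation.
    """
    wl = float(wavelength)
    if not math.isfinite(wl) or wl <= 0:
        raise InvalidInputError(f"wavelength must be finite and > 0, got {wavelength}")
    return complex(_effective_r(stack, np.asarray([wl]))[0])


def reflectance_two_layer_closed(
    n0: float,
    n1: float,
    n2: float,
    n3: float,
    d1: float,
    d2: float,
    wavelength: float | np.ndarray,
):
    """Closed-form reflectance E = A/B of ambient | film 1 | film 2 | substrate.

    A and B are the expanded squared magnitudes of the numerator and
    denominator of the two-layer amplitude ratio

        r = (r01 + r12·x + r23·x·y + r01·r12·r23·y) /
            (1 + r01·r12·x + r12·r23·y + r01·r23·x·y),

    with x = e^{-2iδ1}, y = e^{-2iδ2}, δᵢ = 2π nᵢ dᵢ/λ.  Spelled out in
    cosines of the round-trip phases:

        A = r01² + r12² + r23² + r01²r12²r23²
            + 2 r01 r12 (1 + r23²) cos 2δ1
            + 2 r12 r23 (1 + r01²) cos 2δ2
            + 2 r01 r23 cos(2δ1 + 2δ2)
            + 2 r01 r12² r23 cos(2δ1 − 2δ2)
        B = 1 + r01²r12² + r12²r23² + r01²r23²
            + 2 r01 r12 (1 + r23²) cos 2δ1
            + 2 r12 r23 (1 + r01²) cos 2δ2
            + 2 r01 r23 cos(2δ1 + 2δ2)
            + 2 r01 r12² r23 cos(2δ1 − 2δ2)

    (A and B share their cosine structure; they differ in the constant
    terms.)  Returns a scalar for scalar λ, an array for array λ.
    """
    for nm, v in (("n0", n0), ("n1", n1), ("n2", n2), ("n3", n3)):
        if float(v) <= 0:
            raise InvalidInputError(f"{nm} must be > 0, got {v}")
    if d1 < 0 or d2 < 0:
        raise InvalidInputError("thicknesses must be >= 0")
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl <= 0):
        raise InvalidInputError("wavelength must be > 0")

    r01 = fresnel_amplitude(n0, n1)
    r12 = fresnel_amplitude(n1, n2)
    r23 = fresnel_amplitude(n2, n3)
    two_d1 = 4.0 * np.pi * n1 * d1 / wl  # 2δ1
    two_d2 = 4.0 * np.pi * n2 * d2 / wl  # 2δ2

    cross = (
        2 * r01 * r12 * (1 + r23**2) * np.cos(two_d1)
        + 2 * r12 * r23 * (1 + r01**2) * np.cos(two_d2)
        + 2 * r01 * r23 * np.cos(two_d1 + two_d2)
        + 2 * r01 * r12**2 * r23 * np.cos(two_d1 - two_d2)
    )
    a = r01**2 + r12**2 + r23**2 + (r01 * r12 * r23) ** 2 + cross
    b = 1 + (r01 * r12) ** 2 + (r12 * r23) ** 2 + (r01 * r23) ** 2 + cross
    e = a / b
    if not np.all(np.isfinite(e)):
        raise InvalidInputError("non-finite reflectance; check stack parameters")
    return float(e) if np.isscalar(wavelength) else e


def simulate_spectrum(stack: LayerStack, grid: WavelengthGrid) -> Spectrum:
    """Reflectance spectrum |r_eff(λ)|² of a stack over a wavelength grid.

    Deterministic; dispersionless indices unless a layer carries a
    wavelength → index callable.
    """
    r = _effective_r(stack, grid.wavelengths)
    return Spectrum(grid=grid, values=np.abs(r) ** 2, kind="reflectance")
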