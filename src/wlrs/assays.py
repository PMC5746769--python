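"""Synthetic binding/swelling/scanning experiments and assay analytics.

The generator half of this module produces the time-resolved data an
instrument would record, so every analysis path in the package is testable
without hardware:

* :func:`simulate_binding` — 1:1 Langmuir kinetics: the adlayer grows in
  proportion to fractional surface occupancy,
  d(t) = d_max · [k_on C/(k_on C + k_off)] · (1 − e^{−(k_on C + k_off)t}),
  with an optional dissociation phase (C = 0) continuing from the current
  occupancy;
* :func:`simulate_swelling` — first-order relaxation of a polymer film
  sorbing a vapour, then desorbing symmetrically;
* :func:`sensorgram_to_spectra` — drives the optical forward model with a
  sensorgram, adding multiplicative Gaussian noise, to produce the raw
  material for the fitting round trip;
* :func:`simulate_scan` — a stage scan across spotted reagent bands,
  modelled as top-hat bands convolved with a Gaussian probe spot.

The analytics half quantifies assays: endpoint and initial-rate signals,
four-parameter-logistic calibration with a blank ± 3·SD limit of detection,
chip-regeneration statistics and band extraction from scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import erf

from .errors import InvalidInputError
from .fitting import Sensorgram
from .optics import LayerStack, Spectrum, WavelengthGrid, simulate_spectrum

__all__ = [
    "BindingParams",
    "CalibrationCurve",
    "ScanLayout",
    "simulate_binding",
    "simulate_swelling",
    "sensorgram_to_spectra",
    "endpoint_signal",
    "initial_rate",
    "four_parameter_logistic",
    "build_calibration",
    "regeneration_stats",
    "RegenerationStats",
    "simulate_scan",
    "extract_band_signals",
    "BandSignals",
]


@dataclass(frozen=True)
class BindingParams:
    """1:1 Langmuir binding constants.

    k_on in 1/(M·s), k_off in 1/s, analyte concentration in M, and d_max the
    adlayer thickness (nm) at full surface saturation.  K_D = k_off/k_on.
    """

    k_on: float
    k_off: float
    analyte_conc: float
    d_max: float

    def __post_init__(self) -> None:
        for name, v in (
            ("k_on", self.k_on),
            ("k_off", self.k_off),
            ("analyte_conc", self.analyte_conc),
        ):
            if v < 0 or not math.isfinite(v):
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v}")
        if self.d_max <= 0:
            raise InvalidInputError(f"d_max must be > 0, got {self.d_max}")

    @property
    def k_d(self) -> float:
        if self.k_on == 0:
            return math.inf
        return self.k_off / self.k_on

    @property
    def equilibrium_thickness(self) -> float:
        """Plateau thickness d_max·C/(C + K_D)."""
        c, kd = self.analyte_conc, self.k_d
        if c == 0:
            return 0.0
        return self.d_max * c / (c + kd)


def simulate_binding(
    params: BindingParams,
    times: np.ndarray,
    dissociation_start: float | None = None,
) -> Sensorgram:
    """Langmuir association (and optional dissociation) sensorgram.

    Association: d(t) = d_eq · (1 − e^{−k_obs t}) with
    k_obs = k_on·C + k_off and d_eq the equilibrium thickness.  If
    ``dissociation_start`` is given, the analyte is removed at that time and
    the layer decays as d(t_d)·e^{−k_off (t − t_d)}.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InvalidInputError("times must be a non-empty 1-D array")
    if t[0] < 0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
        raise InvalidInputError("times must be increasing and start at >= 0")
    k_obs = params.k_on * params.analyte_conc + params.k_off
    d_eq = params.equilibrium_thickness
    if k_obs == 0:
        assoc = np.zeros_like(t)
    else:
        assoc = d_eq * (1.0 - np.exp(-k_obs * t))
    if dissociation_start is None:
        return Sensorgram(times=t, thickness=assoc)
    t_d = float(dissociation_start)
    if k_obs == 0:
        d_at_td = 0.0
    else:
        d_at_td = d_eq * (1.0 - math.exp(-k_obs * t_d))
    thickness = np.where(
        t <= t_d, assoc, d_at_td * np.exp(-params.k_off * (t - t_d))
    )
    return Sensorgram(times=t, thickness=thickness)


def simulate_swelling(
    equilibrium_swelling: float,
    tau: float,
    baseline: float,
    times: np.ndarray,
    desorption_start: float | None = None,
) -> Sensorgram:
    """Polymer-film swelling sensorgram as a first-order relaxation.

    On vapour exposure the film thickness relaxes exponentially (time
    constant ``tau``, seconds) from ``baseline`` towards
    baseline·(1 + equilibrium_swelling); on vapour removal at
    ``desorption_start`` it relaxes back with the same time constant.
    """
    if tau <= 0:
        raise InvalidInputError(f"tau must be > 0, got {tau}")
    if baseline <= 0:
        raise InvalidInputError(f"baseline must be > 0, got {baseline}")
    t = np.asarray(times, dtype=float)
    amplitude = baseline * equilibrium_swelling
    sorb = baseline + amplitude * (1.0 - np.exp(-t / tau))
    if desorption_start is None:
        return Sensorgram(times=t, thickness=sorb)
    t_d = float(desorption_start)
    d_at_td = baseline + amplitude * (1.0 - math.exp(-t_d / tau))
    desorb = baseline + (d_at_td - baseline) * np.exp(-(t - t_d) / tau)
    return Sensorgram(times=t, thickness=np.where(t <= t_d, sorb, desorb))


def sensorgram_to_spectra(
    sg: Sensorgram,
    stack: LayerStack,
    grid: WavelengthGrid,
    noise_sd: float,
    seed: int,
    adlayer: str = "adlayer",
) -> list[tuple[float, Spectrum]]:
    """Render a sensorgram as a timestamped reflectance-spectrum series.

    At each time point the named adlayer's thickness is set to the
    sensorgram value, the forward model is evaluated, and per-wavelength
    independent multiplicative Gaussian noise of fractional SD ``noise_sd``
    is applied.  Bit-reproducible for a given seed.
    """
    if adlayer not in stack.layer_names:
        raise InvalidInputError(f"stack has no layer named {adlayer!r}")
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    series = []
    for t, d in zip(sg.times, sg.thickness):
        spec = simulate_spectrum(stack.with_layer_thickness(adlayer, float(d)), grid)
        values = spec.values
        if noise_sd > 0:
            values = values * (1.0 + noise_sd * rng.standard_normal(values.shape))
        series.append((float(t), Spectrum(grid=grid, values=values, kind="reflectance")))
    return series


def endpoint_signal(sg: Sensorgram, t_end: float) -> float:
    """Thickness change between t = 0 and ``t_end`` (linear interpolation)."""
    t = sg.times
    if not (t[0] <= t_end <= t[-1]):
        raise InvalidInputError(f"t_end={t_end} outside sensorgram range [{t[0]}, {t[-1]}]")
    d_end = float(np.interp(t_end, t, sg.thickness))
    return d_end - float(sg.thickness[0])


def initial_rate(sg: Sensorgram, window: float) -> float:
    """Least-squares slope of thickness vs time over the first ``window`` s."""
    t = sg.times
    if window > t[-1] - t[0]:
        raise InvalidInputError("window exceeds sensorgram duration")
    mask = t <= t[0] + window
    if int(mask.sum()) < 3:
        raise InvalidInputError("need at least 3 samples inside the rate window")
    slope = np.polyfit(t[mask], sg.thickness[mask], 1)[0]
    return float(slope)


def four_parameter_logistic(x, a: float, b: float, c: float, d: float):
    """4PL dose–response: y = d + (a − d)/(1 + (x/c)^b).

    ``a`` is the response at zero dose, ``d`` the response at infinite dose,
    ``c`` the midpoint (EC50/IC50) and ``b`` the slope.  Evaluates to ``a``
    exactly at x = 0 (b > 0).
    """
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(x > 0, (x / c) ** b, 0.0)
    return d + (a - d) / (1.0 + ratio)


def _invert_4pl(y: float, a: float, b: float, c: float, d: float) -> float:
    """Dose at which the fitted 4PL predicts response ``y``."""
    frac = (a - d) / (y - d) - 1.0
    if frac <= 0:
        return math.nan
    return c * frac ** (1.0 / b)


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted concentration → response relation with its detection limit.

    ``model_params`` is the 4PL tuple (a, b, c, d); ``lod`` the analyte
    concentration whose predicted response departs from the blank mean by
    ``lod_sd_multiplier`` blank SDs (in the direction the format dictates).
    ``lod_is_bound`` marks an LOD clipped to the calibrated range, and
    ``degenerate_blank`` a zero blank SD.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    model_params: tuple[float, float, float, float]
    lod: float
    mode: str = "endpoint"
    format: str = "direct"
    lod_sd_multiplier: float = 3.0
    lod_is_bound: bool = False
    degenerate_blank: bool = False
    monotone: bool = True

    def predict(self, x):
        return four_parameter_logistic(x, *self.model_params)


FORMATS = ("direct", "two_site", "competitive")


def build_calibration(
    concentrations: np.ndarray,
    responses: np.ndarray,
    format: str = "direct",
    mode: str = "endpoint",
    lod_sd_multiplier: float = 3.0,
) -> CalibrationCurve:
    """Fit a four-parameter logistic calibration curve and estimate the LOD.

    Replicate responses are allowed (repeat the concentration value).  A
    zero calibrator must be present: its replicates define the blank mean
    and SD, and the LOD is the concentration whose predicted response equals
    blank mean + k·SD (direct/two-site) or blank mean − k·SD (competitive),
    k = ``lod_sd_multiplier``.  An LOD falling outside the calibrated range
    is clipped and flagged; a zero blank SD yields a degenerate, flagged
    LOD of 0.
    """
    if format not in FORMATS:
        raise InvalidInputError(f"format must be one of {FORMATS}, got {format!r}")
    conc = np.asarray(concentrations, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise InvalidInputError("concentrations and responses must be 1-D and equal length")
    unique = np.unique(conc)
    if unique.size < 5:
        raise InvalidInputError("need at least 5 distinct concentrations")
    if 0.0 not in unique:
        raise InvalidInputError("a zero calibrator (blank) is required")
    if np.any(conc < 0):
        raise InvalidInputError("concentrations must be >= 0")

    blank = resp[conc == 0]
    blank_mean = float(np.mean(blank))
    blank_sd = float(np.std(blank, ddof=1)) if blank.size > 1 else 0.0

    pos = unique[unique > 0]
    top_mean = float(np.mean(resp[conc == unique[-1]]))
    c0 = float(np.sqrt(pos[0] * pos[-1]))  # geometric midpoint start
    p0 = (blank_mean, 1.0, c0, top_mean)
    lo = [-np.inf, 1e-6, pos[0] * 1e-6, -np.inf]
    hi = [np.inf, 50.0, pos[-1] * 1e6, np.inf]
    params, _ = curve_fit(
        four_parameter_logistic, conc, resp, p0=p0, bounds=(lo, hi), maxfev=20000
    )
    a, b, c, d = (float(v) for v in params)

    # direction check: fitted curve must run the way the format dictates
    increasing = d > a
    if format == "competitive":
        monotone = not increasing
    else:
        monotone = increasing

    degenerate = blank_sd == 0.0
    sign = -1.0 if format == "competitive" else 1.0
    y_crit = blank_mean + sign * lod_sd_multiplier * blank_sd
    lod_is_bound = False
    if degenerate:
        lod = 0.0
    else:
        lod = _invert_4pl(y_crit, a, b, c, d)
        if math.isnan(lod) or lod > pos[-1]:
            lod = float(pos[-1])
            lod_is_bound = True
        elif lod < pos[0]:
            # below the lowest non-zero calibrator: report extrapolated value
            pass
    return CalibrationCurve(
        concentrations=conc,
        responses=resp,
        model_params=(a, b, c, d),
        lod=float(lod),
        mode=mode,
        format=format,
        lod_sd_multiplier=lod_sd_multiplier,
        lod_is_bound=lod_is_bound,
        degenerate_blank=degenerate,
        monotone=monotone,
    )


@dataclass(frozen=True)
class RegenerationStats:
    """Chip reuse quality across assay/regeneration cycles."""

    cv_percent: float
    deviations_percent: np.ndarray  # per-cycle % deviation from cycle 1
    max_abs_deviation_percent: float
    within_tolerance: bool
    tolerance_percent: float


def regeneration_stats(
    cycle_responses: np.ndarray, tolerance_percent: float = 5.0
) -> RegenerationStats:
    """CV% across cycles and per-cycle % deviation from the first cycle.

    Quantifies whether a regenerated chip keeps delivering signals within
    ±``tolerance_percent`` of the fresh-surface value.
    """
    x = np.asarray(cycle_responses, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("need at least 2 cycles")
    mean = float(np.mean(x))
    if mean == 0:
        raise InvalidInputError("mean response is zero; CV undefined")
    cv = float(np.std(x, ddof=1) / mean * 100.0)
    dev = (x - x[0]) / x[0] * 100.0
    max_dev = float(np.max(np.abs(dev)))
    return RegenerationStats(
        cv_percent=cv,
        deviations_percent=dev,
        max_abs_deviation_percent=max_dev,
        within_tolerance=max_dev <= tolerance_percent,
        tolerance_percent=tolerance_percent,
    )


@dataclass(frozen=True)
class ScanLayout:
    """Geometry of spotted reagent bands and the scanning probe.

    Band *i* occupies [i·pitch, i·pitch + width] mm along the scan axis.
    ``band_responses`` are the per-band plateau signals (nm).
    """

    band_width: float = 0.5
    band_pitch: float = 1.0
    n_bands: int = 7
    probe_spot_fwhm: float = 0.4
    step: float = 0.25
    band_responses: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.band_pitch < self.band_width:
            raise InvalidInputError("pitch must be >= band width")
        if self.step <= 0:
            raise InvalidInputError("step must be > 0")
        if self.n_bands < 1:
            raise InvalidInputError("need at least one band")
        if self.probe_spot_fwhm < 0:
            raise InvalidInputError("probe spot FWHM must be >= 0")
        resp = self.band_responses
        if resp is None:
            resp = tuple(1.0 for _ in range(self.n_bands))
        else:
            resp = tuple(float(v) for v in resp)
            if len(resp) != self.n_bands:
                raise InvalidInputError("band_responses length must equal n_bands")
        object.__setattr__(self, "band_responses", resp)

    def band_edges(self, i: int) -> tuple[float, float]:
        start = i * self.band_pitch
        return (start, start + self.band_width)

    @property
    def span(self) -> float:
        return (self.n_bands - 1) * self.band_pitch + self.band_width


def simulate_scan(
    layout: ScanLayout, noise_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stage scan across the spotted bands: positions (mm) and signals (nm).

    The ideal profile is a sum of top-hat bands; the probe spot is a
    Gaussian of the stated FWHM, so each band contributes its response times
    ½·[erf((x − left)/(σ√2)) − erf((x − right)/(σ√2))], σ = FWHM/2√(2 ln 2).
    A zero-width spot reproduces the exact top-hat.  Multiplicative Gaussian
    noise of fractional SD ``noise_sd`` is applied per sample.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    margin = 2.0 * layout.band_pitch + 3.0 * layout.probe_spot_fwhm
    positions = np.arange(-margin, layout.span + margin + layout.step / 2, layout.step)
    sigma = layout.probe_spot_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    signal = np.zeros_like(positions)
    for i in range(layout.n_bands):
        left, right = layout.band_edges(i)
        h = layout.band_responses[i]
        if sigma == 0:
            signal += h * ((positions >= left) & (positions < right))
        else:
            z = sigma * math.sqrt(2.0)
            signal += h * 0.5 * (erf((positions - left) / z) - erf((positions - right) / z))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal * (1.0 + noise_sd * rng.standard_normal(signal.shape))
    return positions, signal


@dataclass(frozen=True)
class BandSignals:
    """Per-band mean responses extracted from a scan profile."""

    band_means: np.ndarray
    cv_percent: float
    overlap_flag: bool
    contrast: float


def extract_band_signals(
    positions: np.ndarray,
    signals: np.ndarray,
    layout: ScanLayout,
    contrast_threshold: float = 0.1,
) -> BandSignals:
    """Per-band mean response (central half of each band) and between-band CV.

    Resolution is judged by the modulation contrast between band plateaus
    and the gaps separating adjacent bands,
    (plateau − gap)/(plateau + gap); a contrast below
    ``contrast_threshold`` raises the overlap flag — the probe spot has
    merged the bands and per-band signals are unreliable.
    """
    pos = np.asarray(positions, dtype=float)
    sig = np.asarray(signals, dtype=float)
    if pos.shape != sig.shape or pos.ndim != 1:
        raise InvalidInputError("positions and signals must be 1-D and equal length")
    if pos[0] > layout.band_edges(0)[0] or pos[-1] < layout.band_edges(layout.n_bands - 1)[1]:
        raise InvalidInputError("scan does not cover all bands")

    means = []
    for i in range(layout.n_bands):
        left, right = layout.band_edges(i)
        quarter = layout.band_width / 4.0
        mask = (pos >= left + quarter) & (pos <= right - quarter)
        if not mask.any():
            raise InvalidInputError(f"no samples in the central half of band {i}")
        means.append(float(np.mean(sig[mask])))
    means_arr = np.asarray(means)
    mean_of_means = float(np.mean(means_arr))
    cv = (
        float(np.std(means_arr, ddof=1) / mean_of_means * 100.0)
        if layout.n_bands > 1 and mean_of_means != 0
        else 0.0
    )

    # contrast: plateau vs the minimum in each gap between band centres
    contrast = 1.0
    if layout.n_bands > 1:
        contrasts = []
        for i in range(layout.n_bands - 1):
            gap_lo = layout.band_edges(i)[1]
            gap_hi = layout.band_edges(i + 1)[0]
            if gap_hi <= gap_lo:  # contiguous bands: no gap to judge
                continue
            gmask = (pos >= gap_lo) & (pos <= gap_hi)
            if not gmask.any():
                continue
            gap_min = float(np.min(sig[gmask]))
            plateau = 0.5 * (means_arr[i] + means_arr[i + 1])
            denom = plateau + gap_min
            contrasts.append((plateau - gap_min) / denom if denom != 0 else 0.0)
        if contrasts:
            contrast = float(np.min(contrasts))
    return BandSignals(
        band_means=means_arr,
        cv_percent=cv,
        overlap_flag=contrast < contrast_threshold,
        contrast=contrast,
    )
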