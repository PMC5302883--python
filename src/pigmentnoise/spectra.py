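"""Microspectrophotometry: absorbance spectra, λ_max, and chromophore exchange.

Optical density follows Beer's law, OD = log10(I_incident / I_transmitted).
Spectra are baseline-corrected by subtracting a line fitted to a long-
wavelength region where the pigment does not absorb, and normalized to the
α-band peak.  Chromophore exchange (replacement of the native 11-cis retinal
by exogenous 9-cis retinal in darkness) is quantified by unmixing each
spectrum as a non-negative linear combination of polynomial templates for the
pure 11-cis and 9-cis pigments, and its time course is fitted with a
saturating exponential a·(1 − e^(−t/τ)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy import optimize, signal

from .errors import DataError, DegenerateSignalError, DomainError, NumericalError

#: Default long-wavelength region (nm) used for baseline fitting; suitable for
#: pigments peaking at or below ~570 nm.
DEFAULT_BASELINE_RANGE = (650.0, 700.0)

#: Default wavelength window (nm) searched for the α-band peak.
DEFAULT_ALPHA_BAND = (380.0, 650.0)

#: Default unmixing range (nm) for long-wavelength-sensitive (LWS) pigments.
DEFAULT_UNMIX_RANGE = (510.0, 750.0)


@dataclass
class AbsorbanceSpectrum:
    """Optical density on a strictly increasing wavelength grid (nm)."""

    wavelengths: np.ndarray
    od: np.ndarray
    normalized: bool = False
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.wavelengths.size != self.od.size:
            raise DataError("wavelength and OD arrays must have equal length")
        if self.wavelengths.size < 2:
            raise DataError("spectrum needs at least two points")
        if (np.diff(self.wavelengths) <= 0).any():
            raise DataError("wavelengths must be strictly increasing")

    def crop(self, lo: float, hi: float) -> "AbsorbanceSpectrum":
        mask = (self.wavelengths >= lo) & (self.wavelengths <= hi)
        if not mask.any():
            raise DataError(f"spectrum has no points in [{lo}, {hi}] nm")
        return AbsorbanceSpectrum(
            self.wavelengths[mask], self.od[mask], self.normalized, self.baseline_corrected
        )


@dataclass
class TemplatePair:
    """Polynomial templates for the 11-cis and 9-cis forms of a pigment.

    Each template is a degree-10 polynomial fitted on a domain rescaled to
    [−1, 1] (``numpy.polynomial.Polynomial`` keeps the mapping), valid inside
    ``fit_range``.
    """

    poly_11cis: Polynomial
    poly_9cis: Polynomial
    fit_range: tuple[float, float] = DEFAULT_UNMIX_RANGE


@dataclass
class ExchangeTimeCourse:
    """Fraction of 9-cis-conjugated pigment versus incubation time."""

    times: np.ndarray            # min, non-negative increasing
    fraction_9cis: np.ndarray    # dimensionless
    sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_9cis = np.asarray(self.fraction_9cis, dtype=float)
        if self.times.size != self.fraction_9cis.size:
            raise DataError("time and fraction arrays must have equal length")
        if (self.times < 0).any() or (np.diff(self.times) < 0).any():
            raise DataError("times must be non-negative and non-decreasing")
        if ((self.fraction_9cis < -0.1) | (self.fraction_9cis > 1.1)).any():
            raise DataError("fractions must lie within [-0.1, 1.1]")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.size != self.times.size:
                raise DataError("sd array must match time points")


@dataclass
class ExchangeKinetics:
    """Saturating-exponential fit a·(1 − e^(−t/τ)) of an exchange time course."""

    asymptote: float             # dimensionless
    tau: float                   # min
    asymptote_se: float = float("nan")
    tau_se: float = float("nan")

    def __post_init__(self) -> None:
        if not self.asymptote > 0:
            raise DataError("asymptote must be > 0")
        if not self.tau > 0:
            raise DataError("time constant must be > 0")


def absorbance(I_incident: float | np.ndarray, I_transmitted: float | np.ndarray) -> float | np.ndarray:
    """Beer's-law optical density OD = log10(I_incident / I_transmitted)."""
    I_i = np.asarray(I_incident, dtype=float)
    I_t = np.asarray(I_transmitted, dtype=float)
    if (I_i <= 0).any() or (I_t <= 0).any():
        raise DomainError("intensities must be strictly positive")
    out = np.log10(I_i / I_t)
    return float(out) if out.ndim == 0 else out


def baseline_correct(
    spectrum: AbsorbanceSpectrum,
    baseline_range: tuple[float, float] = DEFAULT_BASELINE_RANGE,
) -> AbsorbanceSpectrum:
    """Subtract a line fitted over the non-absorbing long-wavelength region."""
    lo, hi = baseline_range
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if mask.sum() < 2:
        raise DataError(f"baseline region [{lo}, {hi}] nm has fewer than 2 points")
    line = Polynomial.fit(spectrum.wavelengths[mask], spectrum.od[mask], deg=1)
    corrected = spectrum.od - line(spectrum.wavelengths)
    return AbsorbanceSpectrum(
        spectrum.wavelengths, corrected, spectrum.normalized, baseline_corrected=True
    )


def normalize_peak(
    spectrum: AbsorbanceSpectrum,
    alpha_band: tuple[float, float] = DEFAULT_ALPHA_BAND,
) -> AbsorbanceSpectrum:
    """Divide by the α-band maximum so the peak OD equals 1; idempotent."""
    lo, hi = alpha_band
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not mask.any():
        raise DataError(f"spectrum has no points in the α-band [{lo}, {hi}] nm")
    peak = float(spectrum.od[mask].max())
    if peak <= 0:
        raise DegenerateSignalError("α-band peak OD is not positive")
    return AbsorbanceSpectrum(
        spectrum.wavelengths,
        spectrum.od / peak,
        normalized=True,
        baseline_corrected=spectrum.baseline_corrected,
    )


def estimate_lambda_max(
    spectrum: AbsorbanceSpectrum,
    alpha_band: tuple[float, float] = DEFAULT_ALPHA_BAND,
    fit_halfwidth: float = 12.0,
    smooth_points: int = 7,
) -> float:
    """Peak-absorption wavelength with sub-grid resolution.

    The spectrum is lightly smoothed (Savitzky-Golay), the raw maximum is
    located inside ``alpha_band``, and a quadratic is fitted over
    ±``fit_halfwidth`` nm around it; the parabola vertex is returned.
    Translation-equivariant and invariant to OD scaling.
    """
    lo, hi = alpha_band
    mask = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if mask.sum() < 5:
        raise DataError("too few points in the α-band to locate a peak")
    wl = spectrum.wavelengths[mask]
    od = spectrum.od[mask]
    win = min(smooth_points if smooth_points % 2 else smooth_points + 1, od.size - (od.size + 1) % 2)
    smoothed = signal.savgol_filter(od, win, polyorder=3) if win >= 5 else od
    i_peak = int(np.argmax(smoothed))
    if i_peak == 0 or i_peak == wl.size - 1:
        raise DataError("α-band peak lies on the boundary of the search range")
    center = wl[i_peak]
    local = (wl >= center - fit_halfwidth) & (wl <= center + fit_halfwidth)
    if local.sum() < 3:
        raise DataError("too few points around the peak for a quadratic fit")
    quad = Polynomial.fit(wl[local], od[local], deg=2)
    c = quad.convert().coef
    if c[2] >= 0:  # not concave; fall back to the smoothed grid maximum
        return float(center)
    vertex = -c[1] / (2 * c[2])
    if not (center - fit_halfwidth <= vertex <= center + fit_halfwidth):
        return float(center)
    return float(vertex)


def fit_template(
    spectrum: AbsorbanceSpectrum,
    degree: int = 10,
    fit_range: tuple[float, float] | None = None,
) -> tuple[Polynomial, float]:
    """Least-squares polynomial template of a mean spectrum.

    Fitted on a domain rescaled to [−1, 1] to keep the degree-10 Vandermonde
    system well conditioned.  Returns the polynomial and R² inside the range.
    """
    sub = spectrum if fit_range is None else spectrum.crop(*fit_range)
    if sub.wavelengths.size < degree + 1:
        raise DataError(
            f"need at least {degree + 1} points for a degree-{degree} fit, "
            f"got {sub.wavelengths.size}"
        )
    poly = Polynomial.fit(sub.wavelengths, sub.od, deg=degree)
    resid = sub.od - poly(sub.wavelengths)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((sub.od - sub.od.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return poly, r2


def unmix_fraction(
    spectrum: AbsorbanceSpectrum,
    templates: TemplatePair,
    fit_range: tuple[float, float] | None = None,
) -> float:
    """Fraction of 9-cis-conjugated pigment by non-negative linear unmixing.

    The spectrum inside the fit range is approximated as
    c11·template_11cis + c9·template_9cis with c11, c9 ≥ 0 (non-negative
    least squares); the reported fraction is c9 / (c11 + c9).
    """
    rng = fit_range or templates.fit_range
    sub = spectrum.crop(*rng)
    design = np.column_stack(
        [templates.poly_11cis(sub.wavelengths), templates.poly_9cis(sub.wavelengths)]
    )
    coeffs, _ = optimize.nnls(design, sub.od)
    c11, c9 = float(coeffs[0]), float(coeffs[1])
    if c11 + c9 == 0.0:
        raise DegenerateSignalError("both template coefficients are zero; fraction undefined")
    return c9 / (c11 + c9)


def saturating_exponential(t: np.ndarray, a: float, tau: float) -> np.ndarray:
    """a·(1 − e^(−t/τ)); shared by the exchange fit and the simulator."""
    return a * -np.expm1(-np.asarray(t, dtype=float) / tau)


def fit_exchange_kinetics(timecourse: ExchangeTimeCourse) -> ExchangeKinetics:
    """Fit a·(1 − e^(−t/τ)) to an exchange time course (a and τ both free).

    Plain least squares; parameter standard errors come from the covariance
    of the fit.
    """
    t = timecourse.times
    y = timecourse.fraction_9cis
    if t.size < 3:
        raise DataError("need at least 3 time points to fit two parameters")
    a0 = max(float(y.max()), 0.1)
    tau0 = max(float(t.max()) / 3.0, 1e-3)
    try:
        popt, pcov = optimize.curve_fit(
            saturating_exponential,
            t,
            y,
            p0=(a0, tau0),
            bounds=((1e-6, 1e-6), (2.0, np.inf)),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise NumericalError(f"exchange-kinetics fit did not converge: {exc}") from exc
    a_se, tau_se = np.sqrt(np.diag(pcov))
    return ExchangeKinetics(
        asymptote=float(popt[0]),
        tau=float(popt[1]),
        asymptote_se=float(a_se),
        tau_se=float(tau_se),
    )


def bleach_fraction(I: float, P: float, t: float) -> float:
    """Bleached pigment fraction F = 1 − e^(−I·P·t).

    I: bleaching light intensity (photons µm^-2 s^-1); P: photosensitivity
    (µm^2); t: exposure (s).  Shares the 1 − e^(−x) form with the photon-
    capture probability :func:`pigmentnoise.events.success_probability`.
    """
    if I < 0 or P < 0 or t < 0:
        raise DomainError("intensity, photosensitivity and time must be >= 0")
    return -float(math.expm1(-I * P * t))


def retinal_concentration(
    od_peak: float, path_cm: float = 1.0, epsilon: float = 36100.0
) -> float:
    """Chromophore concentration (M) from peak absorbance via Beer-Lambert,
    c = OD / (ε · l), with ε = 36,100 M^-1 cm^-1 for 9-cis retinal at 373 nm."""
    if od_peak < 0:
        raise DomainError("optical density must be >= 0")
    if not path_cm > 0 or not epsilon > 0:
        raise DomainError("path length and extinction coefficient must be > 0")
    return od_peak / (epsilon * path_cm)
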