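"""Synthetic data with the statistical structure the analyses assume.

The generator stands in for real recordings: dark traces are homogeneous
Poisson trains of single-photon-response-shaped events on Gaussian
instrumentation noise passed through the acquisition low-pass filter;
dim-flash ensembles capture photons with Poisson statistics; absorbance
spectra follow an A1 visual-pigment nomogram α-band with baseline noise; and
chromophore-exchange time courses follow a saturating exponential.  Every
generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .containers import CurrentTrace, EventList, FlashEnsemble, SinglePhotonResponse
from .errors import DataError, DomainError
from .filtering import lowpass_zero_phase
from .spectra import AbsorbanceSpectrum, ExchangeTimeCourse, saturating_exponential

DEFAULT_SAMPLING_RATE = 1000.0   # Hz
DEFAULT_ACQ_FILTER_HZ = 20.0
#: White-noise SD (pA) before the acquisition filter for a 1 pA quantal
#: amplitude; chosen so the event signal-to-noise ratio is ~5 at the 20 Hz
#: acquisition bandwidth (~14 after the 3 Hz counting filter), the regime in
#: which quantal events are cleanly identifiable by eye in GCAPs-knockout rod
#: recordings and the 30%-amplitude criterion discriminates reliably.
DEFAULT_NOISE_SD = 1.0


def make_spr_template(
    peak_amplitude: float = 1.0,
    time_to_peak: float = 0.3,
    recovery_tau: float = 0.3,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
) -> SinglePhotonResponse:
    """Smooth unimodal single-photon response template.

    f(t) = a · (t/t_p)^q · e^((t_p − t)/τ) with q = t_p/τ, which peaks at
    exactly a at t = t_p and recovers with time constant τ.  Its integration
    time has the closed form  T_i = e^q · Γ(q+1) · τ · (τ/t_p)^q.  The
    defaults give T_i ≈ 0.82 s, in the range of GCAPs-knockout mouse rod
    responses.
    """
    if peak_amplitude <= 0 or time_to_peak <= 0 or recovery_tau <= 0:
        raise DomainError("template parameters must be > 0")
    q = time_to_peak / recovery_tau
    t_end = time_to_peak + 15.0 * recovery_tau
    t = np.arange(0.0, t_end, 1.0 / sampling_rate)
    with np.errstate(divide="ignore"):
        waveform = peak_amplitude * (t / time_to_peak) ** q * np.exp(
            (time_to_peak - t) / recovery_tau
        )
    waveform[0] = 0.0
    ti = float(
        np.exp(q + gammaln(q + 1.0)) * recovery_tau * (recovery_tau / time_to_peak) ** q
    )
    return SinglePhotonResponse(
        waveform=waveform,
        sampling_rate=sampling_rate,
        amplitude=peak_amplitude,
        integration_time=ti,
        peak_time=time_to_peak,
    )


@dataclass
class TraceSimConfig:
    """Configuration for a simulated dark recording."""

    duration: float = 600.0                  # s
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    event_rate: float = 0.005                # s^-1
    spr_template: SinglePhotonResponse | None = None
    continuous_noise_sd: float = DEFAULT_NOISE_SD   # pA, white, pre-filter
    acquisition_filter_hz: float = DEFAULT_ACQ_FILTER_HZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sampling_rate <= 0:
            raise DomainError("duration and sampling_rate must be > 0")
        if self.event_rate < 0 or self.continuous_noise_sd < 0:
            raise DomainError("event_rate and noise SD must be >= 0")
        if self.spr_template is None:
            self.spr_template = make_spr_template(sampling_rate=self.sampling_rate)


@dataclass
class SpectrumSimConfig:
    """Configuration for a simulated absorbance spectrum."""

    lambda_max: float = 500.0                # nm
    template_form: str = "govardovskii"      # or 'loggauss'
    peak_od: float = 1.0
    noise_sd: float = 0.01                   # OD units, per scan
    n_scans: int = 10
    baseline_slope: float = 0.0              # OD per nm
    baseline_offset: float = 0.0             # OD
    grid: np.ndarray = field(
        default_factory=lambda: np.arange(300.0, 701.0, 2.0)
    )
    seed: int = 0


def simulate_dark_trace(config: TraceSimConfig) -> tuple[CurrentTrace, EventList]:
    """Simulate a dark recording and return it with its ground-truth events.

    Event onsets are a homogeneous Poisson process at ``event_rate``; each
    event adds one single-photon template.  White Gaussian noise is added and
    the whole trace is passed through the acquisition low-pass filter.
    Ground-truth times are the event peak times.
    """
    rng = np.random.default_rng(config.seed)
    spr = config.spr_template
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    template = spr.waveform
    t_template = template.size / fs

    onset_span = max(config.duration - t_template, 0.0)
    n_events = rng.poisson(config.event_rate * config.duration)
    onsets = np.sort(rng.uniform(0.0, onset_span, size=n_events))
    # enforce strictly increasing peak times (exact ties have measure zero
    # but the container requires strict order)
    onsets = np.unique(onsets)

    clean = np.zeros(n)
    for onset in onsets:
        i0 = int(round(onset * fs))
        i1 = min(i0 + template.size, n)
        clean[i0:i1] += template[: i1 - i0]

    raw = clean + rng.normal(0.0, config.continuous_noise_sd, size=n)
    filtered = lowpass_zero_phase(raw, fs, config.acquisition_filter_hz)
    trace = CurrentTrace(filtered, fs, filter_cutoff=config.acquisition_filter_hz)

    truth = EventList(
        times=onsets + spr.peak_time,
        amplitudes=np.full(onsets.size, spr.amplitude),
        integration_times=np.full(onsets.size, spr.integration_time),
        duration=config.duration,
    )
    return trace, truth


def simulate_flash_ensemble(
    A_e: float,
    I: float,
    n_trials: int,
    spr: SinglePhotonResponse | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    pre_flash_s: float = 0.5,
    acquisition_filter_hz: float = DEFAULT_ACQ_FILTER_HZ,
) -> FlashEnsemble:
    """Simulate repeated dim-flash trials with Poisson photon capture.

    Each trial absorbs N ~ Poisson(A_e·I) photons and responds with N times
    the single-photon template, plus filtered Gaussian noise.  The fraction
    of non-zero trials converges to p_s = 1 − e^(−A_e·I).
    """
    if A_e < 0 or I < 0:
        raise DomainError("collecting area and intensity must be >= 0")
    if n_trials < 1:
        raise DomainError("need at least one trial")
    rng = np.random.default_rng(seed)
    spr = spr or make_spr_template()
    fs = spr.sampling_rate
    n_pre = int(round(pre_flash_s * fs))
    n = n_pre + spr.waveform.size

    trials = []
    for _ in range(n_trials):
        photons = rng.poisson(A_e * I)
        samples = np.zeros(n)
        samples[n_pre:] = photons * spr.waveform
        samples += rng.normal(0.0, noise_sd, size=n)
        samples = lowpass_zero_phase(samples, fs, acquisition_filter_hz)
        trials.append(CurrentTrace(samples, fs, filter_cutoff=acquisition_filter_hz))
    return FlashEnsemble(trials=trials, flash_intensity=I, flash_time=pre_flash_s)


def _govardovskii_alpha(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1-pigment α-band nomogram (Govardovskii et al. 2000 parametrization)."""
    x = lambda_max / wavelengths
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    denom = np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D
    peak_denom = np.exp(A * (a - 1.0)) + np.exp(B * (b - 1.0)) + np.exp(C * (c - 1.0)) + D
    return peak_denom / denom  # normalized to exactly 1 at λ = λ_max


def _loggauss_alpha(
    wavelengths: np.ndarray, lambda_max: float, width: float = 0.06
) -> np.ndarray:
    """Log-Gaussian α-band fallback: exp(−ln²(λ/λ_max) / (2·width²))."""
    return np.exp(-(np.log(wavelengths / lambda_max) ** 2) / (2.0 * width**2))


def pigment_template_spectrum(
    lambda_max: float,
    grid: np.ndarray | None = None,
    form: str = "govardovskii",
    peak_od: float = 1.0,
) -> AbsorbanceSpectrum:
    """Noise-free normalized α-band absorbance template peaking at λ_max."""
    grid = np.arange(300.0, 701.0, 2.0) if grid is None else np.asarray(grid, dtype=float)
    if not grid[0] <= lambda_max <= grid[-1]:
        raise DomainError("lambda_max must lie within the wavelength grid")
    if form == "govardovskii":
        od = _govardovskii_alpha(grid, lambda_max)
    elif form == "loggauss":
        od = _loggauss_alpha(grid, lambda_max)
    else:
        raise DataError(f"unknown template form {form!r}")
    return AbsorbanceSpectrum(grid, peak_od * od, normalized=(peak_od == 1.0))


def simulate_spectrum(config: SpectrumSimConfig) -> AbsorbanceSpectrum:
    """Simulate a single-cell absorbance measurement.

    The pigment template is tilted by a linear baseline and perturbed by
    Gaussian scan noise averaged over ``n_scans`` scans.
    """
    rng = np.random.default_rng(config.seed)
    template = pigment_template_spectrum(
        config.lambda_max, config.grid, form=config.template_form, peak_od=config.peak_od
    )
    baseline = config.baseline_offset + config.baseline_slope * (
        template.wavelengths - template.wavelengths[0]
    )
    noise = rng.normal(
        0.0, config.noise_sd / np.sqrt(config.n_scans), size=template.wavelengths.size
    )
    return AbsorbanceSpectrum(template.wavelengths, template.od + baseline + noise)


def simulate_exchange_timecourse(
    a: float,
    tau: float,
    times: np.ndarray,
    noise_sd: float = 0.05,
    n_cells: int = 9,
    seed: int = 0,
) -> ExchangeTimeCourse:
    """Simulate a mean chromophore-exchange time course over ``n_cells`` cells.

    Point means follow a·(1 − e^(−t/τ)) with Gaussian error of SD
    noise_sd/√n_cells (the standard error of a cell average).
    """
    if a <= 0 or tau <= 0:
        raise DomainError("kinetic parameters must be > 0")
    if n_cells < 1:
        raise DomainError("need at least one cell")
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    se = noise_sd / np.sqrt(n_cells)
    fractions = saturating_exponential(times, a, tau) + rng.normal(0.0, se, size=times.size)
    return ExchangeTimeCourse(
        times=times,
        fraction_9cis=np.clip(fractions, -0.1, 1.1),
        sd=np.full(times.size, noise_sd),
    )
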