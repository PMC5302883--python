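"""Rate estimation from the power spectrum of dark-current fluctuations.

Spontaneous activations form a Poisson shot process: events of waveform f(t)
occurring at rate r.  By Campbell's theorem the one-sided power spectral
density of that process is 2·r·|F(ν)|², where F is the Fourier transform of
f.  Subtracting the spectrum of an event-free ("quiet") segment from the
spectrum of the full recording removes the continuous instrumentation noise,
leaving the event spectrum, which is fitted with a scaled power spectrum of
the single-photon response.  With the template spectrum computed as the
periodogram of f over one acquisition window of length T, the fitted scale
factor equals r·T, so rate = scale / T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import CurrentTrace, RateEstimate, SinglePhotonResponse
from .errors import DataError, DegenerateSignalError

DEFAULT_SEGMENT_S = 8.192
DEFAULT_OVERLAP = 0.5
DEFAULT_FIT_BAND = (0.1, 5.0)


@dataclass
class PowerSpectrumRecord:
    """One-sided power spectral density on a uniform frequency grid."""

    frequencies: np.ndarray      # Hz, starting at 0, spacing 1/segment_length
    density: np.ndarray          # pA^2 / Hz
    segment_length: float        # s
    overlap_fraction: float
    n_segments: int

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.frequencies.size != self.density.size:
            raise DataError("frequency and density arrays must match")
        if (self.frequencies < 0).any():
            raise DataError("frequencies must be non-negative")

    @property
    def df(self) -> float:
        return 1.0 / self.segment_length


def welch_psd(
    trace: CurrentTrace,
    segment_length: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
) -> PowerSpectrumRecord:
    """Averaged one-sided periodogram (Welch, Hann window, density scaling).

    Normalized so that the integral of the density over frequency equals the
    signal variance (Parseval, up to window correction).
    """
    if trace.duration < segment_length:
        raise DataError("trace shorter than one spectral segment")
    nperseg = int(round(segment_length * trace.sampling_rate))
    noverlap = int(round(nperseg * overlap))
    # no per-segment detrending: a constant offset cancels exactly in the
    # difference spectrum, whereas removing each segment's mean also removes
    # part of every event's power from the lowest frequency bins
    freqs, density = signal.welch(
        trace.samples,
        fs=trace.sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
    )
    step = nperseg - noverlap
    n_segments = 1 + (trace.n_samples - nperseg) // step
    return PowerSpectrumRecord(
        frequencies=freqs,
        density=density,
        segment_length=nperseg / trace.sampling_rate,
        overlap_fraction=overlap,
        n_segments=int(n_segments),
    )


def difference_spectrum(
    full: PowerSpectrumRecord, quiet: PowerSpectrumRecord
) -> PowerSpectrumRecord:
    """Bin-wise difference full − quiet; negative bins are preserved."""
    if full.frequencies.size != quiet.frequencies.size or not np.allclose(
        full.frequencies, quiet.frequencies
    ):
        raise DataError("spectra must share an identical frequency grid")
    return PowerSpectrumRecord(
        frequencies=full.frequencies,
        density=full.density - quiet.density,
        segment_length=full.segment_length,
        overlap_fraction=full.overlap_fraction,
        n_segments=min(full.n_segments, quiet.n_segments),
    )


def select_quiet_segment(trace: CurrentTrace, length: float) -> CurrentTrace:
    """Contiguous sub-trace of the requested length with minimum variance.

    An automated surrogate for picking an event-free stretch by eye: discrete
    events inflate local variance, so the minimum-variance window avoids
    them.  Candidate start points are scanned on a grid of ~length/8 steps.
    """
    if trace.duration < length:
        raise DataError("trace shorter than the requested quiet segment")
    if trace.duration == length:
        return trace
    n = int(round(length * trace.sampling_rate))
    step = max(1, n // 8)
    starts = np.arange(0, trace.n_samples - n + 1, step)
    # O(1) sliding variance via cumulative sums
    c1 = np.concatenate([[0.0], np.cumsum(trace.samples)])
    c2 = np.concatenate([[0.0], np.cumsum(trace.samples**2)])
    sums = c1[starts + n] - c1[starts]
    sqs = c2[starts + n] - c2[starts]
    variances = sqs / n - (sums / n) ** 2
    best = int(starts[np.argmin(variances)])
    return CurrentTrace(
        trace.samples[best : best + n], trace.sampling_rate, trace.filter_cutoff
    )


def spr_power_spectrum(
    spr: SinglePhotonResponse,
    segment_length: float = DEFAULT_SEGMENT_S,
    window: str = "hann",
) -> PowerSpectrumRecord:
    """Expected acquisition-window power spectrum of one single-photon event.

    The waveform is zero-padded to the segment length and its periodogram is
    averaged over all cyclic placements within the window (computed in closed
    form as the cyclic convolution of |F|² with the window's spectral kernel
    |W|²).  This is exactly the per-event contribution a Welch estimate with
    the same window sees for events at random positions, so the scale factor
    fitted against a difference spectrum equals rate × window length without
    window bias.  With ``window='boxcar'`` the record reduces to the plain
    periodogram 2|F(ν)|²/T.
    """
    fs = spr.sampling_rate
    n = int(round(segment_length * fs))
    if spr.waveform.size > n:
        raise DataError("single-photon response longer than the spectral segment")
    padded = np.zeros(n)
    padded[: spr.waveform.size] = spr.waveform
    w = signal.get_window(window, n)
    F2 = np.abs(np.fft.fft(padded)) ** 2
    W2 = np.abs(np.fft.fft(w)) ** 2
    # E|DFT(w · shifted f)|^2 = (1/N^2) (|W|^2 ⊛ |F|^2); the window kernel
    # |W|^2 has only a handful of significant bins (1 for boxcar, 3 for a
    # periodic Hann), so the cyclic convolution is summed explicitly over its
    # support to avoid FFT round-off on the spectrum's huge dynamic range.
    support = np.flatnonzero(W2 > 1e-12 * W2.max())
    conv = np.zeros(n)
    for m in support:
        conv += W2[m] * np.roll(F2, m)
    # density scaling as in scipy: 2 E|DFT|^2 / (fs · Σw²), one-sided with
    # DC/Nyquist undoubled
    density_two_sided = conv / (n**2 * fs * np.sum(w**2))
    half = n // 2
    density = 2.0 * density_two_sided[: half + 1]
    density[0] /= 2.0
    if n % 2 == 0:
        density[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return PowerSpectrumRecord(
        frequencies=freqs,
        density=density,
        segment_length=n / fs,
        overlap_fraction=0.0,
        n_segments=1,
    )


def fit_rate_from_psd(
    diff: PowerSpectrumRecord,
    spr: SinglePhotonResponse,
    acquisition_s: float = DEFAULT_SEGMENT_S,
    fit_band: tuple[float, float] = DEFAULT_FIT_BAND,
) -> RateEstimate:
    """Event rate from the difference spectrum.

    Least-squares scale factor s* of the single-photon power spectrum onto
    the difference spectrum over ``fit_band`` (DC bin excluded); the rate is
    s*/acquisition time.  A negative fitted scale is reported as rate 0.
    """
    if spr.degenerate or not np.any(spr.waveform != 0):
        raise DegenerateSignalError("cannot fit a zero single-photon template")
    template = spr_power_spectrum(spr, segment_length=acquisition_s)
    if template.frequencies.size != diff.frequencies.size or not np.allclose(
        template.frequencies, diff.frequencies
    ):
        raise DataError(
            "difference spectrum and template must share a frequency grid; "
            "compute the data spectra with the same segment length"
        )
    lo, hi = fit_band
    band = (diff.frequencies >= lo) & (diff.frequencies <= hi) & (diff.frequencies > 0)
    if not band.any():
        raise DataError("fit band contains no frequency bins")
    p = template.density[band]
    d = diff.density[band]
    denom = float(np.dot(p, p))
    if denom == 0.0:
        raise DegenerateSignalError("template spectrum vanishes in the fit band")
    scale = float(np.dot(p, d)) / denom
    rate = max(scale, 0.0) / acquisition_s
    # raw_rate keeps the sign: averaging unclipped per-cell estimates is the
    # unbiased way to pool cells when single-cell estimates straddle zero
    return RateEstimate(
        rate=rate,
        method="psd",
        n=diff.n_segments,
        extra={
            "scale": scale,
            "raw_rate": scale / acquisition_s,
            "negative_scale": scale < 0,
            "fit_band": fit_band,
        },
    )


def psd_rate(
    trace: CurrentTrace,
    spr: SinglePhotonResponse,
    segment_length: float = DEFAULT_SEGMENT_S,
    overlap: float = DEFAULT_OVERLAP,
    quiet_length: float = 60.0,
    fit_band: tuple[float, float] = DEFAULT_FIT_BAND,
) -> RateEstimate:
    """Full difference-spectrum pipeline on one dark recording.

    Welch spectrum of the whole trace minus that of the quietest
    ``quiet_length`` seconds, fitted with the single-photon power spectrum.
    """
    full = welch_psd(trace, segment_length, overlap)
    quiet = welch_psd(select_quiet_segment(trace, quiet_length), segment_length, overlap)
    diff = difference_spectrum(full, quiet)
    return fit_rate_from_psd(diff, spr, acquisition_s=full.segment_length, fit_band=fit_band)
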