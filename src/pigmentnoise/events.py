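"""Quantal-event analysis of dark-current recordings.

Spontaneous pigment activations produce discrete current deflections shaped
like the single-photon response (SPR).  This module estimates the SPR from a
dim-flash ensemble (variance-to-mean ratio at the transient peak), detects
quantal events in dark recordings by amplitude and kinetics criteria, and
converts event counts into cellular and per-molecule activation rates,
including a Poisson analysis of counts in fixed-length epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .containers import CurrentTrace, EventList, FlashEnsemble, RateEstimate, SinglePhotonResponse
from .errors import DataError, DegenerateSignalError, DomainError
from .filtering import lowpass_zero_phase
from .thermal import PIGMENTS_PER_ROD, cellular_rate_from_molecular, molecular_rate  # noqa: F401

__all__ = [
    "EventCriteria",
    "EpochCounts",
    "single_photon_response",
    "integration_time",
    "detect_events",
    "counting_rate",
    "epoch_counts",
    "poisson_fit",
    "poisson_pmf",
    "molecular_rate",
    "cellular_rate_from_molecular",
    "collecting_area",
    "success_probability",
]


@dataclass(frozen=True)
class EventCriteria:
    """Acceptance criteria for candidate quantal events.

    An event must exceed ``amplitude_fraction`` of the cell's single-photon
    amplitude (default 30%) and have an integration time within
    ``ti_window`` times the dim-flash integration time (default 50-200%),
    both evaluated on the trace low-pass filtered at
    ``counting_filter_cutoff`` (default 3 Hz).  ``segment_fraction`` is the
    detector's candidate-segmentation threshold, stated as a fraction of the
    filtered single-photon amplitude.
    """

    amplitude_fraction: float = 0.30
    ti_window: tuple[float, float] = (0.5, 2.0)
    counting_filter_cutoff: float = 3.0
    segment_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.amplitude_fraction < 1:
            raise DomainError("amplitude_fraction must lie in (0, 1)")
        lo, hi = self.ti_window
        if not 0 < lo < hi:
            raise DomainError("ti_window must satisfy 0 < low < high")
        if not self.counting_filter_cutoff > 0:
            raise DomainError("counting_filter_cutoff must be > 0")
        if not 0 < self.segment_fraction <= self.amplitude_fraction:
            raise DomainError(
                "segment_fraction must lie in (0, amplitude_fraction]"
            )


@dataclass
class EpochCounts:
    """Event counts in consecutive fixed-length epochs of a dark recording."""

    epoch_length: float          # s
    counts: np.ndarray           # non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 0).any():
            raise DataError("epoch counts must be non-negative")
        if not self.epoch_length > 0:
            raise DataError("epoch_length must be > 0")

    @property
    def n_epochs(self) -> int:
        return int(self.counts.size)

    @property
    def w(self) -> float:
        """Mean events per epoch (the Poisson MLE)."""
        if self.counts.size == 0:
            raise DataError("no epochs to average")
        return float(self.counts.mean())


def integration_time(waveform: np.ndarray, sampling_rate: float) -> float:
    """Integration time of a response: time integral divided by peak amplitude.

    For a rectangular pulse this is the pulse width; for a·e^(−t/τ) it is τ.
    """
    w = np.asarray(waveform, dtype=float)
    if w.size == 0 or not np.any(w > 0):
        raise DegenerateSignalError("waveform has no positive peak")
    peak = float(w.max())
    area = float(np.trapezoid(w, dx=1.0 / sampling_rate))
    return area / peak


def single_photon_response(ensemble: FlashEnsemble) -> SinglePhotonResponse:
    """Estimate the single-photon response from a dim-flash trial ensemble.

    The quantal amplitude a is the ensemble variance-to-mean ratio of the
    trial currents at the time of the mean-response transient peak (single
    sample; ties broken by earliest time).  The returned waveform is the mean
    response scaled to peak at a.  With Poisson photon capture the peak
    current is a·N with N ~ Poisson(λ), so Var/Mean = a independent of λ.
    """
    if len(ensemble.trials) < 2:
        raise DataError("variance-to-mean estimate needs at least 2 trials")
    fs = ensemble.sampling_rate
    arr = ensemble.as_array()

    i_flash = int(round(ensemble.flash_time * fs))
    if i_flash > 0:
        # remove per-trial baseline offsets using the pre-flash window
        arr = arr - arr[:, :i_flash].mean(axis=1, keepdims=True)
    post = arr[:, i_flash:]
    mean_resp = post.mean(axis=0)
    if not np.any(mean_resp > 0):
        raise DegenerateSignalError("mean flash response has no positive peak")
    i_peak = int(np.argmax(mean_resp))
    mu = float(mean_resp[i_peak])
    var = float(post[:, i_peak].var(ddof=1))

    if var == 0.0:
        return SinglePhotonResponse(
            waveform=mean_resp,
            sampling_rate=fs,
            amplitude=0.0,
            integration_time=integration_time(mean_resp, fs),
            peak_time=i_peak / fs,
            degenerate=True,
        )
    if mu == 0.0:
        raise DegenerateSignalError("zero mean response at the transient peak")
    a = var / mu
    waveform = mean_resp * (a / mu)
    return SinglePhotonResponse(
        waveform=waveform,
        sampling_rate=fs,
        amplitude=a,
        integration_time=integration_time(waveform, fs),
        peak_time=i_peak / fs,
    )


def _filtered_template_peak(spr: SinglePhotonResponse, cutoff: float) -> float:
    """Peak of the SPR waveform after the counting filter.

    The template is zero-padded on both sides before filtering so the
    zero-phase filter sees the full transient, keeping the detection
    threshold commensurate with event amplitudes in the filtered trace.
    """
    pad = max(spr.waveform.size, int(2 * spr.sampling_rate / cutoff))
    padded = np.concatenate(
        [np.zeros(pad), spr.waveform * (spr.amplitude / spr.waveform.max()), np.zeros(pad)]
    )
    return float(lowpass_zero_phase(padded, spr.sampling_rate, cutoff).max())


def detect_events(
    trace: CurrentTrace,
    spr: SinglePhotonResponse,
    criteria: EventCriteria | None = None,
) -> EventList:
    """Detect quantal events in a dark recording.

    The trace is low-pass filtered at the counting cutoff; contiguous regions
    above ``segment_fraction`` of the filtered single-photon amplitude are
    candidate events, candidates closer than one dim-flash integration time
    are merged, and each candidate window is extended to the flanking
    zero-crossings before measuring its amplitude and integration time.
    Candidates pass if the amplitude exceeds ``amplitude_fraction`` of the
    filtered single-photon amplitude and the integration time falls within
    ``ti_window`` of the dim-flash integration time.
    """
    criteria = criteria or EventCriteria()
    if spr.degenerate or spr.amplitude <= 0:
        raise DegenerateSignalError("cannot detect events with a degenerate SPR")
    if trace.duration < 10 * spr.integration_time:
        raise DataError("trace shorter than 10 single-photon integration times")

    fs = trace.sampling_rate
    filt = lowpass_zero_phase(trace.samples, fs, criteria.counting_filter_cutoff)
    a_f = _filtered_template_peak(spr, criteria.counting_filter_cutoff)

    seg_thresh = criteria.segment_fraction * a_f
    above = filt > seg_thresh
    labels, n_regions = ndimage.label(above)
    if n_regions == 0:
        return EventList(np.array([]), np.array([]), np.array([]), trace.duration)
    slices = ndimage.find_objects(labels)
    regions = [(s[0].start, s[0].stop) for s in slices]

    # merge candidates separated by less than one dim-flash integration time
    gap = int(spr.integration_time * fs)
    merged: list[list[int]] = [list(regions[0])]
    for start, stop in regions[1:]:
        if start - merged[-1][1] < gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])

    max_ext = int(2 * spr.integration_time * fs)
    times, amps, tis = [], [], []
    for start, stop in merged:
        lo = start
        while lo > 0 and start - lo < max_ext and filt[lo - 1] > 0:
            lo -= 1
        hi = stop
        while hi < filt.size and hi - stop < max_ext and filt[hi] > 0:
            hi += 1
        window = filt[lo:hi]
        amp = float(window.max())
        ti = float(np.trapezoid(np.clip(window, 0.0, None), dx=1.0 / fs) / amp)
        lo_ti, hi_ti = criteria.ti_window
        if amp > criteria.amplitude_fraction * a_f and (
            lo_ti * spr.integration_time <= ti <= hi_ti * spr.integration_time
        ):
            times.append((lo + int(np.argmax(window))) / fs)
            amps.append(amp)
            tis.append(ti)

    if not times:
        return EventList(np.array([]), np.array([]), np.array([]), trace.duration)
    # extended windows may overlap; keep one detection per distinct peak time
    times = np.asarray(times)
    amps = np.asarray(amps)
    tis = np.asarray(tis)
    order = np.argsort(times)
    times, amps, tis = times[order], amps[order], tis[order]
    keep = np.concatenate([[True], np.diff(times) > 0])
    return EventList(times[keep], amps[keep], tis[keep], trace.duration)


def counting_rate(events: EventList, duration: float | None = None) -> RateEstimate:
    """Cellular activation rate by direct counting: events / recording time."""
    duration = events.duration if duration is None else duration
    if not duration > 0:
        raise DomainError("duration must be > 0")
    return RateEstimate(rate=len(events) / duration, method="counting", n=1)


def epoch_counts(
    events: EventList, duration: float | None = None, epoch_length: float = 100.0
) -> EpochCounts:
    """Count events in consecutive full epochs; a trailing partial epoch is
    discarded so every epoch has equal exposure."""
    duration = events.duration if duration is None else duration
    if duration < epoch_length:
        raise DataError("recording shorter than one epoch")
    n_epochs = int(duration // epoch_length)
    edges = np.arange(n_epochs + 1) * epoch_length
    counts, _ = np.histogram(events.times, bins=edges)
    return EpochCounts(epoch_length=epoch_length, counts=counts)


def poisson_fit(counts: EpochCounts) -> tuple[float, float]:
    """Poisson fit of epoch counts: maximum-likelihood mean w (= sample mean)
    and the implied cellular rate w / epoch_length."""
    if counts.n_epochs == 0:
        raise DataError("no epochs to fit")
    w = counts.w
    return w, w / counts.epoch_length


def poisson_pmf(u: int | np.ndarray, w: float) -> float | np.ndarray:
    """Probability p(u) = w^u e^(−w) / u! of observing u events in an epoch."""
    if w < 0:
        raise DomainError("Poisson mean must be >= 0")
    out = stats.poisson.pmf(u, w)
    return float(out) if np.isscalar(u) else out


def success_probability(A_e: float, I: float) -> float:
    """Probability of at least one photoisomerization per flash,
    p_s = 1 − e^(−A_e·I)."""
    if A_e < 0 or I < 0:
        raise DomainError("collecting area and intensity must be >= 0")
    return -float(np.expm1(-A_e * I))


def collecting_area(p_success: float, I: float) -> float:
    """Effective collecting area A_e = −ln(1 − p_s)/I from the dim-flash
    success probability; exact inverse of :func:`success_probability`."""
    if not 0 <= p_success < 1:
        raise DomainError("p_success must lie in [0, 1)")
    if not I > 0:
        raise DomainError("flash intensity must be > 0")
    return -float(np.log1p(-p_success)) / I
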