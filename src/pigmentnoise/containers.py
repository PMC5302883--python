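"""Core data containers for electrophysiological recordings.

Sign convention: quantal events are represented as positive-going deflections
in pA.  Recordings made with the opposite polarity should be negated on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


@dataclass
class CurrentTrace:
    """Uniformly sampled membrane current.

    Parameters
    ----------
    samples : ndarray
        Current in pA at uniform spacing.
    sampling_rate : float
        Hz.
    filter_cutoff : float
        Cutoff (Hz) of the low-pass filter applied during acquisition;
        provenance only, the data are not re-filtered on construction.
    """

    samples: np.ndarray
    sampling_rate: float
    filter_cutoff: float = 20.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise DataError("trace samples must be one-dimensional")
        if not self.sampling_rate > 0:
            raise DataError("sampling_rate must be > 0")
        if not self.sampling_rate > 2 * self.filter_cutoff:
            raise DataError(
                "sampling_rate must exceed twice the acquisition filter cutoff "
                f"(got {self.sampling_rate} Hz vs cutoff {self.filter_cutoff} Hz)"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace length in seconds (n_samples / sampling_rate)."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def segment(self, start_s: float, length_s: float) -> "CurrentTrace":
        """Contiguous sub-trace starting at ``start_s`` of length ``length_s``."""
        i0 = int(round(start_s * self.sampling_rate))
        n = int(round(length_s * self.sampling_rate))
        if i0 < 0 or i0 + n > self.n_samples:
            raise DataError("requested segment extends beyond the trace")
        return CurrentTrace(self.samples[i0 : i0 + n], self.sampling_rate, self.filter_cutoff)


@dataclass
class SinglePhotonResponse:
    """Average single-photon response waveform f(t).

    ``amplitude`` is the quantal amplitude a (pA), estimated as the ensemble
    variance-to-mean ratio at the dim-flash transient peak.  ``waveform`` is
    the mean dim-flash response rescaled so its peak equals a.
    """

    waveform: np.ndarray          # pA, sampled at sampling_rate
    sampling_rate: float          # Hz
    amplitude: float              # pA
    integration_time: float       # s
    peak_time: float = 0.0        # s
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.amplitude < 0:
            raise DataError("quantal amplitude must be >= 0")
        if not self.degenerate and not self.integration_time > 0:
            raise DataError("integration time must be > 0 for a non-degenerate response")


@dataclass
class FlashEnsemble:
    """Repeated dim-flash trials aligned to flash onset."""

    trials: list[CurrentTrace]
    flash_intensity: float = 0.0   # photons µm^-2 flash^-1
    flash_time: float = 0.0        # s, onset within each trial

    def __post_init__(self) -> None:
        if not self.trials:
            raise DataError("flash ensemble contains no trials")
        if self.flash_intensity < 0:
            raise DataError("flash intensity must be >= 0")
        fs = self.trials[0].sampling_rate
        n = self.trials[0].n_samples
        for t in self.trials:
            if t.sampling_rate != fs or t.n_samples != n:
                raise DataError("all trials must share sampling rate and length")

    @property
    def sampling_rate(self) -> float:
        return self.trials[0].sampling_rate

    def as_array(self) -> np.ndarray:
        """(n_trials, n_samples) stack of the trial currents."""
        return np.stack([t.samples for t in self.trials])


@dataclass
class EventList:
    """Detected quantal events: times, amplitudes and integration times."""

    times: np.ndarray              # s, strictly increasing
    amplitudes: np.ndarray         # pA
    integration_times: np.ndarray  # s
    duration: float                # s, of the parent recording

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.integration_times = np.asarray(self.integration_times, dtype=float)
        if not (self.times.size == self.amplitudes.size == self.integration_times.size):
            raise DataError("event arrays must have equal length")
        if self.times.size and (np.diff(self.times) <= 0).any():
            raise DataError("event times must be strictly increasing")
        if self.times.size and (
            self.times[0] < 0 or self.times[-1] > self.duration
        ):
            raise DataError("event times must lie within [0, duration]")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class RateEstimate:
    """A spontaneous-activation rate with its method of origin.

    ``rate`` is in events s^-1 cell^-1 for the trace-based methods; the
    ``molecular`` conversion divides by the pigment count.
    """

    rate: float
    method: str                    # 'counting' | 'poisson' | 'psd'
    n: int = 1                     # cells or epochs contributing
    dispersion: float = float("nan")   # SD across contributors where defined
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise DataError("rate must be >= 0")
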