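"""Low-pass filtering shared by the analysis and the simulator.

The recordings this package targets were acquired through an analog RC
low-pass filter whose order is not critical for the analyses; a second-order
Butterworth applied forward and backward (zero phase, effective fourth order)
is used throughout.  The same routine emulates the acquisition filter in the
synthetic generator and implements the 3 Hz counting filter, so detection
thresholds computed from a filtered template are directly comparable to the
filtered data.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .errors import DataError

FILTER_ORDER = 2  # per pass; filtfilt doubles the effective order


def lowpass_zero_phase(
    x: np.ndarray, sampling_rate: float, cutoff: float, order: int = FILTER_ORDER
) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a 1-D signal.

    ``cutoff`` must lie below the Nyquist frequency.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < cutoff < sampling_rate / 2:
        raise DataError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={sampling_rate / 2} Hz)"
        )
    sos = signal.butter(order, cutoff, btype="low", fs=sampling_rate, output="sos")
    padlen = min(x.size - 1, 3 * int(sampling_rate / cutoff))
    return signal.sosfiltfilt(sos, x, padlen=padlen)
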