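"""Zero-phase Butterworth low-pass filtering of current traces."""

from __future__ import annotations

from scipy import signal

from .models import CurrentTrace


def lowpass_filter(trace: CurrentTrace, cutoff: float = 2000.0,
                   order: int = 4) -> CurrentTrace:
    """Low-pass Butterworth filter, applied forward-backward.

    Zero-phase (``sosfiltfilt``) application keeps event boundaries
    unshifted; the effective magnitude response is |H(f)|^2 of the
    ``order``-th order Butterworth prototype, with unit DC gain.

    Parameters
    ----------
    cutoff : float
        -3 dB corner frequency in Hz; must be below Nyquist.
    """
    nyq = trace.sampling_rate / 2.0
    if not (0 < cutoff < nyq):
        raise ValueError(f"cutoff {cutoff} Hz must lie in (0, Nyquist={nyq})")
    sos = signal.butter(order, cutoff, btype="low", fs=trace.sampling_rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, trace.currents)
    meta = dict(trace.metadata, filtered_cutoff_hz=cutoff, filter_order=order)
    return CurrentTrace(filtered, trace.sampling_rate, meta)
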