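"""Short-time Fourier spectrograms for ultrasonic-vocalization analysis.

The spectrogram is the substrate of every acoustic operation downstream
(call detection, peak-frequency contour tracking, feature extraction).
Defaults follow the standard rodent-USV workflow: a 256-point FFT with a
Hamming window and 50% frame overlap, with all energy below a 20 kHz
cut-off zeroed to suppress audible-band background noise.

Magnitudes (not power, not dB) are stored; conversion to dB happens only
where a threshold is applied or a figure is drawn, with a -120 dB floor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window

DB_FLOOR = -120.0


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency magnitude matrix with axis metadata.

    Attributes
    ----------
    magnitudes : ndarray, shape (n_bins, n_frames)
        Nonnegative STFT magnitudes; ``n_bins == fft_len // 2 + 1``.
    freqs_hz : ndarray
        Bin center frequencies, ``k * sample_rate / fft_len`` (0-based),
        strictly increasing from 0 to Nyquist.
    times_s : ndarray
        Frame center times in seconds.
    sample_rate_hz : float
    fft_len : int
        FFT length in samples; equals the window length (no zero-padding).
    hop : int
        Frame advance in samples.
    window_name : str
    cutoff_hz : float
        Low-frequency cut-off already applied (0 if none).
    """

    magnitudes: np.ndarray
    freqs_hz: np.ndarray
    times_s: np.ndarray
    sample_rate_hz: float
    fft_len: int
    hop: int
    window_name: str = "hamming"
    cutoff_hz: float = 0.0

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[1]

    @property
    def bin_spacing_hz(self) -> float:
        return self.sample_rate_hz / self.fft_len

    @property
    def frame_period_s(self) -> float:
        return self.hop / self.sample_rate_hz

    def to_db(self) -> np.ndarray:
        """Magnitudes in dB (20 log10), floored at -120 dB."""
        return magnitudes_to_db(self.magnitudes)


def magnitudes_to_db(mag: np.ndarray) -> np.ndarray:
    floor_amp = 10.0 ** (DB_FLOOR / 20.0)
    return 20.0 * np.log10(np.maximum(np.asarray(mag, dtype=float), floor_amp))


def n_frames_for(n_samples: int, fft_len: int, hop: int) -> int:
    """Number of full analysis frames: floor((n_samples - fft_len)/hop) + 1."""
    if n_samples < fft_len:
        raise ValueError(
            f"waveform has {n_samples} samples, shorter than one frame ({fft_len})"
        )
    return (n_samples - fft_len) // hop + 1


def compute_spectrogram(
    waveform: np.ndarray,
    sample_rate_hz: float,
    fft_len: int = 256,
    overlap: float = 0.5,
    window: str = "hamming",
) -> Spectrogram:
    """Compute an STFT magnitude spectrogram over full frames only.

    The hop is ``fft_len * (1 - overlap)`` samples and no zero-padding is
    applied beyond the last full frame, so the frame count is exactly
    ``floor((n_samples - fft_len)/hop) + 1``.

    Parameters
    ----------
    waveform : 1-D array of samples.
    sample_rate_hz : sampling rate in Hz.
    fft_len : FFT (and window) length in samples.
    overlap : fractional frame overlap in [0, 1).
    window : window name understood by :func:`scipy.signal.get_window`.

    Raises
    ------
    ValueError
        If the waveform is shorter than one frame or overlap is invalid.
    """
    x = np.asarray(waveform, dtype=float)
    if x.ndim != 1:
        raise ValueError("waveform must be 1-D (mono)")
    if not (0.0 <= overlap < 1.0):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    hop = int(round(fft_len * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("overlap too close to 1: hop would be < 1 sample")
    n = n_frames_for(x.size, fft_len, hop)

    frames = sliding_window_view(x, fft_len)[::hop][:n]
    win = get_window(window, fft_len, fftbins=True)
    mag = np.abs(np.fft.rfft(frames * win, axis=1)).T  # (n_bins, n_frames)

    freqs = np.arange(fft_len // 2 + 1) * (sample_rate_hz / fft_len)
    times = (np.arange(n) * hop + fft_len / 2.0) / sample_rate_hz
    return Spectrogram(
        magnitudes=mag,
        freqs_hz=freqs,
        times_s=times,
        sample_rate_hz=float(sample_rate_hz),
        fft_len=fft_len,
        hop=hop,
        window_name=window,
    )


def apply_cutoff(spec: Spectrogram, cutoff_hz: float = 20000.0) -> Spectrogram:
    """Zero all bins whose center frequency is below ``cutoff_hz``.

    Bins are retained (shapes are stable) and the operation is idempotent.
    The 20 kHz default removes audible-band background noise while leaving
    the ultrasonic call band untouched.
    """
    nyquist = spec.sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist {nyquist} Hz")
    mag = spec.magnitudes.copy()
    mag[spec.freqs_hz < cutoff_hz, :] = 0.0
    return replace(spec, magnitudes=mag, cutoff_hz=max(cutoff_hz, spec.cutoff_hz))


def save_spectrogram_png(spec: Spectrogram, path: str, vmin_db: float = -90.0) -> None:
    """Export a dB spectrogram image (axes in ms / kHz) for inspection."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    db = spec.to_db()
    extent = (
        spec.times_s[0] * 1e3,
        spec.times_s[-1] * 1e3,
        spec.freqs_hz[0] / 1e3,
        spec.freqs_hz[-1] / 1e3,
    )
    im = ax.imshow(
        db, origin="lower", aspect="auto", extent=extent,
        vmin=vmin_db, vmax=db.max(), cmap="magma",
    )
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("frequency (kHz)")
    fig.colorbar(im, ax=ax, label="dB")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
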