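"""Time-frequency feature tensors from multichannel neural signal.

Epochs of 1 s (90% overlap, 0.1 s stride) are decomposed per channel
with a continuous complex Morlet wavelet transform at central
frequencies 10, 20, ..., 150 Hz.  Wavelet magnitudes are averaged in
ten non-overlapping 100 ms windows, yielding one feature tensor
``X^t`` of shape (tau, f, s) = (10, 15, n_channels) per epoch --
9600 scalars at 64 channels.

Two usage patterns are supported:

* :func:`session_features` transforms a full continuous recording
  once and slices the overlapped epochs out of the transform
  (preferred: no per-epoch edge artifacts);
* :func:`morlet_features` transforms a single 1 s epoch with
  reflection padding.
"""

from __future__ import annotations

import numpy as np
import pywt

#: central frequencies of the Morlet filter bank, Hz
FREQS_DEFAULT = np.arange(10.0, 151.0, 10.0)
#: number of non-overlapping averaging windows per 1 s epoch
N_TAU_DEFAULT = 10


def _wavelet_name(n_cycles: float) -> str:
    # pywt's cmorB-C wavelet is exp(-t^2/B) * exp(2*pi*i*C*t); its time
    # std is sqrt(B/2), so B = 2*(n_cycles/(2*pi))^2 gives a product
    # sigma_t * f_c of n_cycles/(2*pi), i.e. ~n_cycles cycles per wavelet.
    bandwidth = 2.0 * (n_cycles / (2.0 * np.pi)) ** 2
    return f"cmor{bandwidth:.8f}-1.0"


def extract_epochs(
    signal: np.ndarray,
    fs: float,
    epoch_len: float = 1.0,
    stride: float = 0.1,
) -> list[tuple[float, slice]]:
    """Slice an overlapped epoch grid out of a continuous recording.

    Parameters
    ----------
    signal : ndarray, shape (n_samples, n_channels)
        Uniformly sampled multichannel signal.
    fs : float
        Sampling rate in Hz.
    epoch_len, stride : float
        Epoch length and spacing in seconds (defaults 1.0 and 0.1,
        i.e. 90% overlap).

    Returns
    -------
    list of (end_time, slice)
        One entry per epoch; ``floor((T - epoch_len)/stride) + 1``
        epochs in total.  Epochs are labeled by their END time.
    """
    signal = np.asarray(signal)
    if signal.ndim == 1:
        signal = signal[:, None]
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal contains non-finite samples")
    if stride > epoch_len:
        raise ValueError("epoch stride must not exceed epoch length")
    n = signal.shape[0]
    duration = n / fs
    if duration < epoch_len - 1e-9:
        raise ValueError(
            f"signal duration {duration:.3f} s shorter than epoch length {epoch_len} s"
        )
    n_epoch = int(np.floor((duration - epoch_len) / stride + 1e-9)) + 1
    win = int(round(epoch_len * fs))
    out = []
    for k in range(n_epoch):
        start = int(round(k * stride * fs))
        stop = min(start + win, n)
        out.append((k * stride + epoch_len, slice(stop - win, stop)))
    return out


def morlet_transform(
    signal: np.ndarray,
    fs: float,
    freqs: np.ndarray = FREQS_DEFAULT,
    n_cycles: float = 7.0,
) -> np.ndarray:
    """Complex Morlet wavelet magnitude of a multichannel signal.

    Returns an array of shape (n_samples, n_freqs, n_channels) of
    non-negative wavelet magnitudes.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim == 1:
        signal = signal[:, None]
    freqs = np.asarray(freqs, dtype=float)
    if np.max(freqs) * 2.0 > fs:
        raise ValueError(
            f"sampling rate {fs} Hz below Nyquist requirement for {np.max(freqs)} Hz"
        )
    name = _wavelet_name(n_cycles)
    # pywt normalized frequency = C / scale; C = 1.0
    scales = fs / freqs
    coefs, _ = pywt.cwt(signal, scales, name, axis=0, method="fft")
    # coefs: (n_freqs, n_samples, n_channels)
    return np.abs(coefs).transpose(1, 0, 2)


def _window_average(mag: np.ndarray, n_tau: int) -> np.ndarray:
    """Average (n_samples, f, s) magnitudes into n_tau equal time windows."""
    n = mag.shape[0]
    bounds = np.round(np.linspace(0, n, n_tau + 1)).astype(int)
    out = np.empty((n_tau, mag.shape[1], mag.shape[2]))
    for k in range(n_tau):
        out[k] = mag[bounds[k] : bounds[k + 1]].mean(axis=0)
    return out


def morlet_features(
    epoch: np.ndarray,
    fs: float,
    freqs: np.ndarray = FREQS_DEFAULT,
    n_tau: int = N_TAU_DEFAULT,
    n_cycles: float = 7.0,
    pad: bool = True,
) -> np.ndarray:
    """Feature tensor of a single 1 s epoch.

    Wavelet magnitude is averaged in ``n_tau`` non-overlapping windows
    that tile the epoch exactly; output shape is
    (n_tau, len(freqs), n_channels).  Reflection padding (half an
    epoch each side) suppresses boundary artifacts of the transform.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim == 1:
        epoch = epoch[:, None]
    n = epoch.shape[0]
    if pad:
        p = n // 2
        padded = np.concatenate([epoch[p:0:-1], epoch, epoch[-2 : -p - 2 : -1]], axis=0)
        mag = morlet_transform(padded, fs, freqs, n_cycles)[p : p + n]
    else:
        mag = morlet_transform(epoch, fs, freqs, n_cycles)
    return _window_average(mag, n_tau)


def session_features(
    signal: np.ndarray,
    fs: float,
    epoch_len: float = 1.0,
    stride: float = 0.1,
    freqs: np.ndarray = FREQS_DEFAULT,
    n_tau: int = N_TAU_DEFAULT,
    n_cycles: float = 7.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature tensors for every overlapped epoch of a recording.

    The whole recording is transformed once, then epochs are sliced
    from the transform, so overlapping epochs share identical wavelet
    coefficients.

    Returns
    -------
    times : ndarray, shape (N,)
        Epoch end times in seconds.
    tensors : ndarray, shape (N, n_tau, n_freqs, n_channels)
    """
    windows = extract_epochs(signal, fs, epoch_len, stride)
    mag = morlet_transform(signal, fs, freqs, n_cycles)
    times = np.array([t for t, _ in windows])
    tensors = np.stack([_window_average(mag[sl], n_tau) for _, sl in windows])
    return times, tensors
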