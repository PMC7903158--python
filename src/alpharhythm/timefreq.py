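"""Moving-window Fourier decomposition, power and inter-trial phase coherence.

Single-trial spectral estimates use a Hann-tapered moving window (0.5 s long,
stepped by 0.05 s) evaluated on a 1-20 Hz grid with 1-Hz resolution. A 0.5-s
window natively resolves 2-Hz spacing, so each window is zero-padded (to 1 s
by default) before the DFT — the common practice to honor a 1-Hz grid.
Coefficients are normalized by the taper's sum, making the magnitude of a
unit sinusoid independent of the window length.

Oscillatory power is the across-trial mean of squared coefficient magnitudes.
Inter-trial phase coherence (ITPC) is the magnitude of the across-trial mean
of unit-normalized coefficients: 1 for perfect phase locking, approaching 0
for uniform phases. Planar-gradiometer pairs are combined per position by
summing power and averaging ITPC.

Window centering: the coefficient at time t uses data from [t-0.25, t+0.25) s;
windows that would extend past the epoch edges yield no estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal.windows import hann

from .errors import ConfigurationError, DataError
from .simulate import SensorLayout

__all__ = [
    "TFDecomposition",
    "PowerMap",
    "ITCMap",
    "stft_decompose",
    "compute_power",
    "compute_itpc",
    "combine_pairs",
    "trial_alpha_power",
]

DEFAULT_FREQS = tuple(float(f) for f in range(1, 21))


@dataclass
class TFDecomposition:
    """Complex moving-window Fourier coefficients, trials x channels x freqs x times."""

    coeffs: np.ndarray
    freqs: np.ndarray  # Hz
    times: np.ndarray  # window centers, s
    channel_names: list[str]

    @property
    def n_trials(self) -> int:
        return self.coeffs.shape[0]


@dataclass
class PowerMap:
    """Trial-averaged oscillatory power, channels x freqs x times (amplitude^2)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    n_trials: int


@dataclass
class ITCMap:
    """Inter-trial phase coherence, channels x freqs x times, in [0, 1]."""

    itpc: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    channel_names: list[str]
    n_trials: int


def _as_int(x: float, what: str) -> int:
    n = int(round(x))
    if abs(x - n) > 1e-6:
        raise ConfigurationError(f"{what} must be an integer number of samples, got {x}")
    return n


def stft_decompose(
    data: np.ndarray,
    sfreq: float,
    times: np.ndarray,
    freqs=DEFAULT_FREQS,
    win_len: float = 0.5,
    step: float = 0.05,
    pad_to: float = 1.0,
    channel_names: list[str] | None = None,
) -> TFDecomposition:
    """Hann-tapered moving-window Fourier coefficients on a fixed frequency grid.

    Parameters
    ----------
    data : trials x channels x samples (a 2-D channels x samples array is
        treated as a single trial).
    freqs : requested frequency grid (Hz). Each frequency must fall on the
        grid achievable with the configured zero-padding (spacing
        ``1 / pad_to`` Hz); otherwise a :class:`ConfigurationError` explains
        the required padding rather than silently rounding.
    """
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataError("data must be trials x channels x samples")
    times = np.asarray(times, dtype=float)
    n_win = _as_int(win_len * sfreq, "window length")
    hop = _as_int(step * sfreq, "step")
    n_pad = _as_int(pad_to * sfreq, "padded length")
    if n_win < 2:
        raise ConfigurationError("window must span at least 2 samples")
    if n_pad < n_win:
        raise ConfigurationError("pad_to must be at least the window length")
    df = sfreq / n_pad
    freqs = np.asarray(freqs, dtype=float)
    bins = freqs / df
    if np.any(np.abs(bins - np.round(bins)) > 1e-6):
        raise ConfigurationError(
            f"requested frequencies {freqs[np.abs(bins - np.round(bins)) > 1e-6]} Hz "
            f"do not fall on the {df:g}-Hz grid; increase pad_to for finer resolution"
        )
    bins = np.round(bins).astype(int)
    if np.any(freqs >= sfreq / 2):
        raise ConfigurationError("requested frequencies must be below Nyquist")

    n_samples = arr.shape[-1]
    if n_samples < n_win:
        raise DataError("epoch shorter than one analysis window")
    window = hann(n_win, sym=False)
    norm = window.sum()
    # fully interior windows only
    segments = sliding_window_view(arr, n_win, axis=-1)[..., ::hop, :]
    spec = np.fft.rfft(segments * window, n=n_pad, axis=-1) / norm
    coeffs = spec[..., bins]  # trials x channels x n_windows x n_freqs
    coeffs = np.moveaxis(coeffs, -1, -2)  # -> trials x channels x freqs x times
    starts = np.arange(segments.shape[-2]) * hop
    centers = times[0] + (starts + n_win / 2.0) / sfreq
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(arr.shape[1])]
    return TFDecomposition(
        coeffs=coeffs, freqs=freqs, times=centers, channel_names=list(channel_names)
    )


def compute_power(tfd: TFDecomposition) -> PowerMap:
    """Across-trial mean of squared coefficient magnitudes."""
    if tfd.n_trials < 1:
        raise DataError("power requires at least one trial")
    power = np.mean(np.abs(tfd.coeffs) ** 2, axis=0)
    return PowerMap(
        power=power,
        freqs=tfd.freqs,
        times=tfd.times,
        channel_names=tfd.channel_names,
        n_trials=tfd.n_trials,
    )


def compute_itpc(tfd: TFDecomposition) -> ITCMap:
    """Magnitude of the across-trial mean of unit-normalized coefficients.

    Zero-magnitude coefficients contribute a zero vector to the mean (they
    remain counted in the number of trials) and trigger a warning.
    """
    if tfd.n_trials < 2:
        raise DataError("ITPC requires at least two trials")
    mags = np.abs(tfd.coeffs)
    zero = mags == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-magnitude coefficients contribute zero "
            "vectors to the ITPC mean",
            stacklevel=2,
        )
    unit = np.where(zero, 0.0, tfd.coeffs / np.where(zero, 1.0, mags))
    itpc = np.abs(unit.mean(axis=0))
    return ITCMap(
        itpc=itpc,
        freqs=tfd.freqs,
        times=tfd.times,
        channel_names=tfd.channel_names,
        n_trials=tfd.n_trials,
    )


def _pair_indices(channel_names: list[str], layout: SensorLayout) -> np.ndarray:
    index = {name: i for i, name in enumerate(channel_names)}
    pairs = []
    for c1, c2 in layout.pair_channels:
        if c1 not in index or c2 not in index:
            raise DataError(f"unpaired or missing channels for position ({c1}, {c2})")
    for c1, c2 in layout.pair_channels:
        pairs.append((index[c1], index[c2]))
    return np.asarray(pairs)


def combine_pairs(tf_map: PowerMap | ITCMap, layout: SensorLayout):
    """Merge planar-gradiometer pairs: sum power, average ITPC, per position."""
    pairs = _pair_indices(tf_map.channel_names, layout)
    if isinstance(tf_map, PowerMap):
        combined = tf_map.power[pairs[:, 0]] + tf_map.power[pairs[:, 1]]
        return PowerMap(
            power=combined,
            freqs=tf_map.freqs,
            times=tf_map.times,
            channel_names=list(layout.positions),
            n_trials=tf_map.n_trials,
        )
    if isinstance(tf_map, ITCMap):
        combined = 0.5 * (tf_map.itpc[pairs[:, 0]] + tf_map.itpc[pairs[:, 1]])
        return ITCMap(
            itpc=combined,
            freqs=tf_map.freqs,
            times=tf_map.times,
            channel_names=list(layout.positions),
            n_trials=tf_map.n_trials,
        )
    raise TypeError("combine_pairs expects a PowerMap or ITCMap")


def trial_alpha_power(
    tfd: TFDecomposition, layout: SensorLayout, band: tuple[float, float] = (8.0, 12.0)
) -> np.ndarray:
    """Per-trial band power at combined positions: trials x positions x times.

    Squared magnitudes are averaged over band frequencies and summed over the
    two raw channels of each position (pair combination before any trial
    averaging), the form needed by the sub-epoch sub-sampling analysis.
    """
    sel = (tfd.freqs >= band[0]) & (tfd.freqs <= band[1])
    if not sel.any():
        raise ConfigurationError(f"band {band} contains no grid frequencies")
    power = np.mean(np.abs(tfd.coeffs[:, :, sel, :]) ** 2, axis=2)
    pairs = _pair_indices(tfd.channel_names, layout)
    return power[:, pairs[:, 0]] + power[:, pairs[:, 1]]
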