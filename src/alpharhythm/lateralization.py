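"""Hemispheric alpha-power lateralization indices.

Two normalized difference indices quantify the deployment of spatial
attention, both bounded in [-1, 1] wherever both power terms are positive:

* topographic lateralization, per sensor:
  (Pow_attend-left - Pow_attend-right) / (Pow_attend-left + Pow_attend-right),
  evaluated on band- and window-averaged power (canonically 8-12 Hz over the
  pre-stimulus 0-1.5 s window);
* time-resolved lateralization, per time step:
  (Pow_ipsilateral - Pow_contralateral) / (Pow_ipsilateral + Pow_contralateral),
  where ipsi/contralateral are hemisphere-mean alpha power relative to the
  attended side (midline sensors excluded).

Power is averaged over the frequency band and sensor set *before* the ratio
is formed (ratio of averages), matching the aggregate power terms of the
index definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError
from .simulate import SensorLayout
from .timefreq import PowerMap

__all__ = [
    "LateralizationSeries",
    "topographic_lateralization",
    "split_hemispheres",
    "timeresolved_lateralization",
]


@dataclass
class LateralizationSeries:
    """A lateralization index over time, with the band and labels it came from."""

    values: np.ndarray  # index per time step; NaN where undefined
    times: np.ndarray
    alpha_band: tuple[float, float]
    cue_type: str | None = None
    attended_side: str | None = None


def _band_window_average(
    pmap: PowerMap, band: tuple[float, float], window: tuple[float, float] | None
) -> np.ndarray:
    """Average power over a frequency band (and optionally a time window)."""
    fsel = (pmap.freqs >= band[0]) & (pmap.freqs <= band[1])
    if not fsel.any():
        raise ConfigurationError(f"band {band} contains no grid frequencies")
    out = pmap.power[:, fsel, :].mean(axis=1)
    if window is not None:
        tsel = (pmap.times >= window[0]) & (pmap.times <= window[1])
        if not tsel.any():
            raise ConfigurationError(f"window {window} contains no time steps")
        out = out[:, tsel].mean(axis=1)
    return out


def _safe_ratio(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    """(a-b)/(a+b) with nonpositive denominators flagged as NaN, not zeroed."""
    bad = ~(den > 0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} {what} with nonpositive total power flagged as NaN",
            stacklevel=3,
        )
    out = np.full(num.shape, np.nan)
    np.divide(num, den, out=out, where=~bad)
    return out


def topographic_lateralization(
    pow_att_left: PowerMap,
    pow_att_right: PowerMap,
    band: tuple[float, float] = (8.0, 12.0),
    window: tuple[float, float] = (0.0, 1.5),
) -> np.ndarray:
    """Per-sensor attend-left vs attend-right alpha lateralization index."""
    if pow_att_left.channel_names != pow_att_right.channel_names:
        raise DataError("the two power maps must share the same channels")
    if pow_att_left.power.shape != pow_att_right.power.shape:
        raise DataError("the two power maps must share the same grid")
    left = _band_window_average(pow_att_left, band, window)
    right = _band_window_average(pow_att_right, band, window)
    return _safe_ratio(left - right, left + right, "sensors")


def split_hemispheres(
    pmap: PowerMap,
    layout: SensorLayout,
    attended_side: str,
    band: tuple[float, float] = (8.0, 12.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Hemisphere-mean alpha-power time courses, mapped to (ipsi, contra).

    Power is band-averaged and then averaged over the left and right sensor
    sets of ``layout`` (midline excluded); the set on the attended side is
    ipsilateral.
    """
    if attended_side not in ("left", "right"):
        raise ConfigurationError(f"attended_side must be left or right, got {attended_side!r}")
    band_power = _band_window_average(pmap, band, None)  # channels x times
    name_to_row = {name: i for i, name in enumerate(pmap.channel_names)}
    series = {}
    for hemi in ("left", "right"):
        members = [
            p for p, h in zip(layout.positions, layout.hemispheres) if h == hemi
        ]
        if not members:
            raise DataError(f"layout has no sensors over the {hemi} hemisphere")
        rows = [name_to_row[m] for m in members if m in name_to_row]
        if len(rows) != len(members):
            raise DataError("power map is missing hemisphere sensors from the layout")
        series[hemi] = band_power[rows].mean(axis=0)
    if attended_side == "left":
        return series["left"], series["right"]
    return series["right"], series["left"]


def timeresolved_lateralization(
    ipsi: np.ndarray,
    contra: np.ndarray,
    times: np.ndarray | None = None,
    alpha_band: tuple[float, float] = (8.0, 12.0),
    **labels,
) -> LateralizationSeries:
    """(ipsi - contra) / (ipsi + contra) per time step."""
    ipsi = np.asarray(ipsi, dtype=float)
    contra = np.asarray(contra, dtype=float)
    if ipsi.shape != contra.shape:
        raise DataError("ipsi and contra series must have equal length")
    values = _safe_ratio(ipsi - contra, ipsi + contra, "time points")
    if times is None:
        times = np.arange(ipsi.size, dtype=float)
    return LateralizationSeries(
        values=values, times=np.asarray(times, dtype=float), alpha_band=alpha_band, **labels
    )
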