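"""Synthetic trial schedules, behavior, and MEG-like recordings.

The generator emulates the statistical structure the sensor-level analysis
assumes, with planted ground-truth parameters so every downstream estimator
can be checked by parameter recovery:

* a balanced trial schedule (instructive vs neutral temporal cues, attend-left
  vs attend-right, graded cued-position counts, 70%-valid probes);
* behavior whose accuracy and response times depend on cue validity;
* epoched multichannel signals in which 8-12 Hz alpha power is hemispherically
  lateralized, the lateralization is sinusoidally modulated at the 0.8-Hz
  stimulus rate (modulation depth differs by cue condition and is boosted
  around the cued number's onset), each number onset adds a phase-locked
  low-frequency transient, and 1/f background noise is superimposed.

Sensors come in planar-gradiometer pairs at combined positions labelled by
hemisphere; the generator emits the raw (pre-combination) channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from . import design
from .errors import ConfigurationError

__all__ = [
    "SensorLayout",
    "GeneratorParams",
    "SimulatedRecording",
    "make_trial_schedule",
    "make_sensor_layout",
    "simulate_behavior",
    "simulate_meg",
    "participant_rng",
]

SCHEDULE_COLUMNS = [
    "trial_id",
    "cue_type",
    "cued_position",
    "attended_side",
    "probed_position",
    "is_valid",
]


@dataclass(frozen=True)
class SensorLayout:
    """Combined-gradiometer positions with hemisphere labels and raw pairs.

    Each combined position carries exactly two raw planar-gradiometer
    channels (``<position>_1``, ``<position>_2``).
    """

    positions: tuple[str, ...]
    hemispheres: tuple[str, ...]  # "left" | "right" | "mid" per position

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.hemispheres):
            raise ConfigurationError("positions and hemispheres must align")
        bad = set(self.hemispheres) - {"left", "right", "mid"}
        if bad:
            raise ConfigurationError(f"unknown hemisphere labels: {bad}")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    @property
    def pair_channels(self) -> list[tuple[str, str]]:
        return [(f"{p}_1", f"{p}_2") for p in self.positions]

    @property
    def channel_names(self) -> list[str]:
        return [ch for pair in self.pair_channels for ch in pair]

    @property
    def channel_hemispheres(self) -> np.ndarray:
        return np.repeat(np.asarray(self.hemispheres, dtype=object), 2)

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        """Boolean mask over combined positions for one hemisphere label."""
        return np.asarray([h == hemisphere for h in self.hemispheres])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos, hemi, (c1, c2) in zip(
            self.positions, self.hemispheres, self.pair_channels
        ):
            rows.append({"position": pos, "hemisphere": hemi, "chan_1": c1, "chan_2": c2})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SensorLayout":
        return cls(
            positions=tuple(frame["position"]),
            hemispheres=tuple(frame["hemisphere"]),
        )


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of the synthetic MEG generator.

    Amplitudes are in T/cm-like field units so that realistic planar
    gradiometer magnitudes (~1e-13) and the conventional 3e-12 ("3 pT/cm")
    rejection threshold remain meaningful.

    ``lat_offset`` is the baseline lateralization L0 of alpha power: the
    hemisphere ipsilateral to the attended side carries power P0*(1 + L(t)),
    the contralateral hemisphere P0*(1 - L(t)), with

        L(t) = L0 + d * cos(2*pi*0.8*(t - t_first_onset - mod_lag_s))

    during number presentation, where d is the condition's modulation depth
    (plus ``cued_boost`` within the cued number's 1.25-s sub-window on
    instructive trials).
    """

    sampling_rate: float = 200.0
    alpha_freq: float = 10.0
    alpha_base_power: float = 1e-26  # P0, squared field units
    lat_offset: float = 0.2
    mod_depth_neutral: float = 0.1
    mod_depth_instructive: float = 0.2
    cued_boost: float = 0.2
    mod_lag_s: float = 0.46  # lag of the lateralization modulation behind onsets
    evoked_amplitude: float = 2e-13
    evoked_freq: float = 3.0
    evoked_duration_s: float = 0.4
    noise_std: float = 1e-13
    noise_exponent: float = 1.0
    p_correct_valid: float = 0.93
    p_correct_invalid: float = 0.79
    p_correct_neutral: float = 0.80
    # per-class response-time lognormal (median seconds, log-space sigma)
    rt_params: dict = field(
        default_factory=lambda: {
            "valid": (0.90, 0.30),
            "invalid": (1.10, 0.30),
            "neutral": (1.00, 0.30),
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_correct_valid", "p_correct_invalid", "p_correct_neutral"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        for name in ("mod_depth_neutral", "mod_depth_instructive", "cued_boost"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.alpha_base_power <= 0:
            raise ConfigurationError("alpha_base_power must be > 0")
        highest = max(self.alpha_freq, self.evoked_freq)
        if self.sampling_rate <= 2.0 * highest:
            raise ConfigurationError(
                f"sampling_rate {self.sampling_rate} Hz must exceed twice the "
                f"highest generated frequency ({highest} Hz)"
            )
        for cls_, (median, sigma) in self.rt_params.items():
            if median <= 0 or sigma < 0:
                raise ConfigurationError(f"invalid rt_params for {cls_!r}")

    def replace(self, **kwargs) -> "GeneratorParams":
        return replace(self, **kwargs)


@dataclass
class SimulatedRecording:
    """Epoched synthetic recording with its schedule, layout and ground truth."""

    epochs: np.ndarray  # trials x raw channels x samples
    time_axis: np.ndarray  # seconds relative to spatial-cue onset
    schedule: pd.DataFrame
    layout: SensorLayout
    ground_truth: GeneratorParams

    @property
    def sampling_rate(self) -> float:
        return self.ground_truth.sampling_rate


def participant_rng(master_seed: int, participant_id: int) -> np.random.Generator:
    """One reproducible pseudo-random stream per (master seed, participant)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(participant_id)])
    )


def _scaled_position_counts(n_instructive_per_side: int) -> dict[int, int]:
    """Cued-position counts per attended side, scaled from the 160-trial design.

    The canonical design cues positions 1-5 on 8/18/28/18/8 of the 80
    instructive trials, i.e. 4/9/14/9/4 per attended side.
    """
    base_per_side = {p: c // 2 for p, c in design.POSITION_CUE_COUNTS.items()}
    base_total = sum(base_per_side.values())  # 40
    scale = n_instructive_per_side / base_total
    counts = {p: c * scale for p, c in base_per_side.items()}
    if any(abs(c - round(c)) > 1e-9 for c in counts.values()):
        raise ConfigurationError(
            f"{2 * base_total * 2 * scale:.0f} trials cannot be partitioned into "
            "the graded cued-position design; use a multiple of "
            f"{4 * base_total} trials"
        )
    return {p: int(round(c)) for p, c in counts.items()}


def make_trial_schedule(
    n_trials: int = design.N_TRIALS_DEFAULT,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Construct a balanced trial schedule.

    The design marginals are constructed exactly, not sampled: half the
    trials carry an instructive temporal cue and half a neutral one; within
    each cue type the attended side is balanced; cued positions among
    instructive trials follow the graded counts (8/18/28/18/8 per 80
    instructive trials, split evenly across sides). Only the probe draw is
    random: instructive trials probe the cued position with probability 0.7
    and otherwise a uniformly drawn other position; neutral trials probe a
    uniformly drawn position.

    Returns a data frame with columns ``trial_id, cue_type, cued_position,
    attended_side, probed_position, is_valid`` (``cued_position`` and
    ``is_valid`` are nullable; not applicable on neutral trials).
    """
    if n_trials <= 0 or n_trials % 4 != 0:
        raise ConfigurationError(
            f"n_trials must be a positive multiple of 4 (cue type x side "
            f"balance), got {n_trials}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_per_cell = n_trials // 4  # per (cue_type, side)
    per_side_counts = _scaled_position_counts(n_per_cell)

    rows: list[dict] = []
    for cue_type in design.CUE_TYPES:
        for side in design.SIDES:
            if cue_type == "instructive":
                cued = [p for p, c in per_side_counts.items() for _ in range(c)]
            else:
                cued = [None] * n_per_cell
            for cp in cued:
                rows.append(
                    {"cue_type": cue_type, "cued_position": cp, "attended_side": side}
                )
    frame = pd.DataFrame(rows)

    # probe assignment: cued position with probability 0.7, otherwise a
    # uniformly drawn one of the remaining four positions
    n_all = len(frame)
    instructive = (frame["cue_type"] == "instructive").to_numpy()
    cued = np.where(instructive, frame["cued_position"].to_numpy(object), 0).astype(int)
    probed = np.empty(n_all, dtype=int)
    valid = rng.random(n_all) < design.CUE_VALIDITY
    # cyclic offset 1..4 from the cued position is uniform over the others
    offsets = rng.integers(1, design.N_POSITIONS, size=n_all)
    probed[instructive] = np.where(
        valid, cued, (cued - 1 + offsets) % design.N_POSITIONS + 1
    )[instructive]
    probed[~instructive] = rng.integers(
        1, design.N_POSITIONS + 1, size=(~instructive).sum()
    )
    frame["probed_position"] = probed
    is_valid = np.full(n_all, pd.NA, dtype=object)
    is_valid[instructive] = valid[instructive]
    frame["is_valid"] = is_valid

    # shuffle presentation order, then assign trial ids in presented order
    order = rng.permutation(len(frame))
    frame = frame.iloc[order].reset_index(drop=True)
    frame.insert(0, "trial_id", np.arange(len(frame)))
    frame["cued_position"] = frame["cued_position"].astype("Int64")
    frame["is_valid"] = frame["is_valid"].astype("boolean")
    return frame[SCHEDULE_COLUMNS]


def validity_class(schedule: pd.DataFrame) -> pd.Series:
    """Per-trial behavioral class: 'valid', 'invalid' or 'neutral'."""
    cls = pd.Series("neutral", index=schedule.index, dtype=object)
    instructive = schedule["cue_type"] == "instructive"
    cls[instructive & (schedule["is_valid"] == True)] = "valid"  # noqa: E712
    cls[instructive & (schedule["is_valid"] == False)] = "invalid"  # noqa: E712
    return cls


def make_sensor_layout(
    n_left: int = 48, n_right: int = 48, n_mid: int = 6
) -> SensorLayout:
    """Build a labelled combined-gradiometer layout (default 48/48/6 = 102)."""
    if min(n_left, n_right, n_mid) < 0:
        raise ConfigurationError("sensor counts must be >= 0")
    positions: list[str] = []
    hemis: list[str] = []
    for hemi, n, tag in (("left", n_left, "L"), ("right", n_right, "R"), ("mid", n_mid, "M")):
        for i in range(n):
            positions.append(f"MEG_{tag}{i:02d}")
            hemis.append(hemi)
    return SensorLayout(positions=tuple(positions), hemispheres=tuple(hemis))


def simulate_behavior(
    schedule: pd.DataFrame,
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-trial correctness and response time.

    Correctness is Bernoulli with the probability of the trial's validity
    class; response times are lognormal with a class-specific median
    (slower medians for invalid cues), hence strictly positive.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    cls = validity_class(schedule)
    p_map = {
        "valid": params.p_correct_valid,
        "invalid": params.p_correct_invalid,
        "neutral": params.p_correct_neutral,
    }
    p = cls.map(p_map).to_numpy(dtype=float)
    correct = rng.random(len(schedule)) < p
    medians = cls.map({k: v[0] for k, v in params.rt_params.items()}).to_numpy(float)
    sigmas = cls.map({k: v[1] for k, v in params.rt_params.items()}).to_numpy(float)
    rt = medians * np.exp(sigmas * rng.standard_normal(len(schedule)))
    return pd.DataFrame(
        {"trial_id": schedule["trial_id"].to_numpy(), "correct": correct, "rt": rt}
    )


def _evoked_kernel(params: GeneratorParams) -> np.ndarray:
    """Hann-windowed low-frequency cycle added at each number onset.

    Identical across trials and channels, so trial phases at 1-5 Hz align
    perfectly at onsets and inter-trial phase coherence is high there.
    """
    n = int(round(params.evoked_duration_s * params.sampling_rate))
    tau = np.arange(n) / params.sampling_rate
    carrier = np.cos(2 * np.pi * params.evoked_freq * (tau - params.evoked_duration_s / 2))
    return params.evoked_amplitude * hann(n, sym=True) * carrier


def _pink_noise(
    rng: np.random.Generator, shape: tuple[int, ...], sfreq: float, exponent: float, std: float
) -> np.ndarray:
    """Gaussian 1/f^exponent noise along the last axis, scaled to ``std``."""
    if std == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1.0 / sfreq)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    spec *= shaping
    noise = np.fft.irfft(spec, n=shape[-1], axis=-1)
    noise *= std / noise.std()
    return noise


def lateralization_profile(
    t: np.ndarray, cue_type: str, cued_position: int | None, params: GeneratorParams
) -> np.ndarray:
    """Planted lateralization time course L(t) for one trial.

    Baseline ``lat_offset`` throughout; during number presentation
    (first onset to last offset) a 0.8-Hz cosine modulation of condition-
    specific depth is added, lagging the number onsets by ``mod_lag_s``.
    On instructive trials the depth is additionally boosted within the cued
    number's 1.25-s sub-window.
    """
    t = np.asarray(t, dtype=float)
    stim_lo = design.FIRST_ONSET_S
    stim_hi = design.FIRST_ONSET_S + design.N_POSITIONS * design.ONSET_INTERVAL_S
    in_stim = (t >= stim_lo) & (t < stim_hi)
    depth = np.zeros_like(t)
    base_depth = (
        params.mod_depth_instructive
        if cue_type == "instructive"
        else params.mod_depth_neutral
    )
    depth[in_stim] = base_depth
    if cue_type == "instructive" and cued_position is not None and params.cued_boost:
        onset = design.number_onset(int(cued_position))
        in_cued = (t >= onset) & (t < onset + design.ONSET_INTERVAL_S)
        depth[in_cued] += params.cued_boost
    phase = 2 * np.pi * design.STIM_RATE_HZ * (t - stim_lo - params.mod_lag_s)
    return params.lat_offset + depth * np.cos(phase)


def simulate_meg(
    schedule: pd.DataFrame,
    layout: SensorLayout,
    params: GeneratorParams,
    rng: np.random.Generator | None = None,
) -> SimulatedRecording:
    """Generate epoched MEG-like data for one participant.

    Per trial, every raw channel over one hemisphere carries an alpha
    oscillation with random (per channel, per trial) carrier phase whose
    instantaneous power is P0*(1 + L(t)) on the side ipsilateral to the
    attended ear and P0*(1 - L(t)) contralaterally; midline channels carry
    unmodulated power P0. Each number onset adds the phase-locked evoked
    transient on all channels, and 1/f noise is superimposed.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    if params.alpha_freq >= fs / 2:
        raise ConfigurationError("alpha_freq must be below the Nyquist frequency")
    t0, t1 = design.EPOCH_WINDOW_S
    n_samples = int(round((t1 - t0) * fs))
    time_axis = t0 + np.arange(n_samples) / fs
    n_trials = len(schedule)
    chan_hemi = layout.channel_hemispheres
    n_chan = chan_hemi.size
    if n_chan == 0:
        raise ConfigurationError("layout has no channels")

    # evoked component, shared by all trials/channels
    evoked = np.zeros(n_samples)
    kernel = _evoked_kernel(params)
    for pos in range(1, design.N_POSITIONS + 1):
        start = int(round((design.number_onset(pos) - t0) * fs))
        stop = min(start + kernel.size, n_samples)
        evoked[start:stop] += kernel[: stop - start]

    is_left = chan_hemi == "left"
    is_right = chan_hemi == "right"
    epochs = np.empty((n_trials, n_chan, n_samples))
    carrier_arg = 2 * np.pi * params.alpha_freq * time_axis  # shared ramp

    for i, row in enumerate(schedule.itertuples(index=False)):
        lat = lateralization_profile(
            time_axis,
            row.cue_type,
            None if pd.isna(row.cued_position) else int(row.cued_position),
            params,
        )
        p_ipsi = params.alpha_base_power * (1.0 + lat)
        p_contra = params.alpha_base_power * (1.0 - lat)
        if row.attended_side == "left":
            p_left, p_right = p_ipsi, p_contra
        else:
            p_left, p_right = p_contra, p_ipsi
        amp = np.empty((n_chan, n_samples))
        amp[is_left] = np.sqrt(p_left)
        amp[is_right] = np.sqrt(p_right)
        amp[~(is_left | is_right)] = math.sqrt(params.alpha_base_power)
        phases = rng.uniform(0.0, 2 * np.pi, size=(n_chan, 1))
        epochs[i] = amp * np.cos(carrier_arg[None, :] + phases) + evoked[None, :]

    epochs += _pink_noise(
        rng, epochs.shape, fs, params.noise_exponent, params.noise_std
    )
    return SimulatedRecording(
        epochs=epochs,
        time_axis=time_axis,
        schedule=schedule.copy(),
        layout=layout,
        ground_truth=params,
    )
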