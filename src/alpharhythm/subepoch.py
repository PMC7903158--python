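"""Number-position sub-epochs and the cued / uncued / neutral sub-sampling.

Each trial is split into sub-epochs around the onsets of number positions
2-4 (positions 1 and 5 are excluded: they are rarely cued and are
contaminated by the spatial cue and by response preparation). A sub-epoch is
labelled *cued* when its trial carried an instructive cue and the position
was the cued one, *uncued* for the other positions of instructive trials,
and *neutral* for all positions of neutral-cue trials.

Cued sub-epochs are by design fewer than uncued or neutral ones. For an
unbiased contrast the uncued/neutral alpha lateralization is therefore
computed on random sub-samples drawn *without replacement* within each
(attended side, number position) cell to exactly the cued counts, repeated
``n_draws`` times (10,000 by default). A participant's cued lateralization
time course is then expressed against this sub-sample distribution as a
z-value per time point, and the group of per-participant z series is tested
against zero with sign-flip permutation tests plus a percentile bootstrap
confidence interval of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import design
from .errors import ConfigurationError, DataError
from .simulate import SensorLayout
from .stats import bootstrap_ci_mean, sign_flip_pvalues

__all__ = [
    "SubEpochSet",
    "SubsampleDistribution",
    "GroupZResult",
    "subepoch_table",
    "extract_subepochs",
    "subepoch_hemi_power",
    "cued_lateralization",
    "subsampled_lateralization",
    "zscore_contrast",
    "group_inference",
]

DEFAULT_POSITIONS = (2, 3, 4)
DEFAULT_WINDOW = (-2.0, 3.25)


@dataclass
class SubEpochSet:
    """Time-domain sub-epochs (n_sub x channels x samples) with their labels."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to number onset
    table: pd.DataFrame  # trial_id, position, attended_side, label, onset


@dataclass
class SubsampleDistribution:
    """Sub-sampled lateralization time courses: n_draws x time points."""

    draws: np.ndarray
    times: np.ndarray
    label: str
    matched_counts: dict  # (side, position) -> count drawn per draw


@dataclass
class GroupZResult:
    """Group-level z series with bootstrap CI and permutation p-values."""

    mean_z: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    times: np.ndarray


def subepoch_table(
    schedule: pd.DataFrame, positions=DEFAULT_POSITIONS
) -> pd.DataFrame:
    """One row per (trial, number position) with its cueing label."""
    rows = []
    for row in schedule.itertuples(index=False):
        for pos in positions:
            if row.cue_type == "neutral":
                label = "neutral"
            elif not pd.isna(row.cued_position) and int(row.cued_position) == pos:
                label = "cued"
            else:
                label = "uncued"
            rows.append(
                {
                    "trial_id": row.trial_id,
                    "position": pos,
                    "attended_side": row.attended_side,
                    "label": label,
                    "onset": design.number_onset(pos),
                }
            )
    return pd.DataFrame(rows)


def extract_subepochs(
    data: np.ndarray,
    times: np.ndarray,
    sfreq: float,
    schedule: pd.DataFrame,
    positions=DEFAULT_POSITIONS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> SubEpochSet:
    """Cut onset-locked sub-epochs out of whole-trial epoched data.

    ``data`` is trials x channels x samples aligned with ``schedule`` rows.
    The window must fit within the parent epoch for every requested position.
    """
    data = np.asarray(data)
    times = np.asarray(times, dtype=float)
    if data.ndim != 3 or data.shape[0] != len(schedule):
        raise DataError("data must be trials x channels x samples matching the schedule")
    n_rel = int(round((window[1] - window[0]) * sfreq))
    table = subepoch_table(schedule, positions)
    trial_row = {tid: i for i, tid in enumerate(schedule["trial_id"])}
    chunks = np.empty((len(table), data.shape[1], n_rel), dtype=data.dtype)
    for i, row in enumerate(table.itertuples(index=False)):
        start_t = row.onset + window[0]
        start = int(round((start_t - times[0]) * sfreq))
        if start < 0 or start + n_rel > data.shape[2]:
            raise DataError(
                f"sub-epoch window {window} around position {row.position} "
                "exceeds the parent epoch"
            )
        chunks[i] = data[trial_row[row.trial_id], :, start : start + n_rel]
    rel_times = window[0] + np.arange(n_rel) / sfreq
    return SubEpochSet(data=chunks, times=rel_times, table=table)


def subepoch_hemi_power(
    trial_power: np.ndarray,
    tf_times: np.ndarray,
    layout: SensorLayout,
    schedule: pd.DataFrame,
    positions=DEFAULT_POSITIONS,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Onset-locked hemisphere-mean alpha power per sub-epoch.

    ``trial_power`` is per-trial combined-position band power
    (trials x positions x TF time steps, as from
    :func:`alpharhythm.timefreq.trial_alpha_power`). Because the moving-window
    decomposition is translation-covariant, slicing the whole-trial power at
    onset-relative time steps is numerically identical to re-decomposing
    time-domain sub-epochs, while covering the full window.

    Returns ``(hemi_power, rel_times, table)`` where ``hemi_power`` is
    n_sub x 2 (left, right hemisphere) x time steps.
    """
    trial_power = np.asarray(trial_power, dtype=float)
    tf_times = np.asarray(tf_times, dtype=float)
    if trial_power.shape[0] != len(schedule):
        raise DataError("trial_power must align with the schedule")
    step = tf_times[1] - tf_times[0]
    left = layout.hemisphere_mask("left")
    right = layout.hemisphere_mask("right")
    if not left.any() or not right.any():
        raise DataError("layout must have sensors over both hemispheres")
    hemi_trials = np.stack(
        [trial_power[:, left].mean(axis=1), trial_power[:, right].mean(axis=1)], axis=1
    )  # trials x 2 x steps
    table = subepoch_table(schedule, positions)
    trial_row = {tid: i for i, tid in enumerate(schedule["trial_id"])}

    # common onset-relative step grid available for all positions
    n_rel = None
    slices = {}
    for pos in positions:
        onset = design.number_onset(pos)
        lo = onset + window[0]
        hi = onset + window[1]
        if tf_times[0] > lo + step * 0.51 or tf_times[-1] < hi - step * 0.51:
            raise DataError(
                f"sub-epoch window {window} around position {pos} exceeds the "
                "available time-frequency support"
            )
        sel = np.where((tf_times >= lo - step * 1e-3) & (tf_times <= hi + step * 1e-3))[0]
        slices[pos] = sel
        n_rel = sel.size if n_rel is None else min(n_rel, sel.size)
    for pos in positions:
        slices[pos] = slices[pos][:n_rel]
    rel_times = tf_times[slices[positions[0]]] - design.number_onset(positions[0])

    hemi = np.empty((len(table), 2, n_rel))
    for i, row in enumerate(table.itertuples(index=False)):
        hemi[i] = hemi_trials[trial_row[row.trial_id], :, slices[row.position]].T
    return hemi, rel_times, table


def _cued_counts(table: pd.DataFrame) -> dict[tuple[str, int], int]:
    cued = table[table["label"] == "cued"]
    counts = cued.groupby(["attended_side", "position"]).size()
    return {(side, int(pos)): int(c) for (side, pos), c in counts.items()}


def _lateralization_of_means(mean_left, mean_right, side: str):
    """Index series from hemisphere-mean power; ipsi is the attended side."""
    if side == "left":
        ipsi, contra = mean_left, mean_right
    else:
        ipsi, contra = mean_right, mean_left
    return (ipsi - contra) / (ipsi + contra)


def cued_lateralization(
    hemi_power: np.ndarray, table: pd.DataFrame
) -> np.ndarray:
    """Cued-sub-epoch lateralization time course (no sub-sampling needed).

    Alpha power is averaged over a participant's cued sub-epochs (across
    positions and trials) separately per attended side, the lateralization
    index formed per side, then averaged across the two sides.
    """
    per_side = []
    for side in design.SIDES:
        mask = (table["label"] == "cued") & (table["attended_side"] == side)
        if not mask.any():
            raise DataError(f"no cued sub-epochs for attend-{side}")
        mean = hemi_power[mask.to_numpy()].mean(axis=0)  # 2 x T
        per_side.append(_lateralization_of_means(mean[0], mean[1], side))
    return np.mean(per_side, axis=0)


def subsampled_lateralization(
    hemi_power: np.ndarray,
    table: pd.DataFrame,
    label: str,
    n_draws: int = 10000,
    seed: int | np.random.Generator = 0,
    times: np.ndarray | None = None,
    chunk: int = 2000,
) -> SubsampleDistribution:
    """Sub-sample distribution of the lateralization index for one label.

    Every draw samples, without replacement within each (attended side,
    number position) cell, exactly as many ``label`` sub-epochs as there are
    cued ones in that cell, then averages alpha power across the drawn
    sub-epochs and positions per side, forms the lateralization index per
    side, and averages the attend-left and attend-right indices.
    """
    if label not in ("uncued", "neutral", "cued"):
        raise ConfigurationError(f"unknown sub-epoch label {label!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = _cued_counts(table)
    n_time = hemi_power.shape[2]
    sides = design.SIDES
    # candidate pools per cell
    pools: dict[tuple[str, int], np.ndarray] = {}
    for (side, pos), need in counts.items():
        pool = np.where(
            (table["label"] == label)
            & (table["attended_side"] == side)
            & (table["position"] == pos)
        )[0]
        if pool.size < need:
            raise DataError(
                f"cell (side={side}, position={pos}) has only {pool.size} "
                f"'{label}' sub-epochs but {need} are required"
            )
        pools[(side, pos)] = pool

    draws = np.empty((n_draws, n_time))
    for start in range(0, n_draws, chunk):
        stop = min(start + chunk, n_draws)
        m = stop - start
        side_means = {}
        for side in sides:
            total = np.zeros((m, 2, n_time))
            n_tot = 0
            for (s, pos), need in counts.items():
                if s != side:
                    continue
                pool = pools[(s, pos)]
                idx = np.argsort(rng.random((m, pool.size)), axis=1)[:, :need]
                total += hemi_power[pool[idx]].sum(axis=1)
                n_tot += need
            side_means[side] = total / n_tot
        lat = np.mean(
            [
                _lateralization_of_means(
                    side_means[s][:, 0], side_means[s][:, 1], s
                )
                for s in sides
            ],
            axis=0,
        )
        draws[start:stop] = lat
    if times is None:
        times = np.arange(n_time, dtype=float)
    return SubsampleDistribution(
        draws=draws, times=np.asarray(times, dtype=float), label=label,
        matched_counts=counts,
    )


def zscore_contrast(
    cued_series: np.ndarray, dist: SubsampleDistribution
) -> np.ndarray:
    """Standardize the cued series against the sub-sample distribution.

    z(t) = (cued(t) - mean_draws(t)) / sd_draws(t); time points with zero
    sub-sample spread are flagged NaN with a warning.
    """
    if dist.draws.shape[0] < 2:
        raise DataError("need at least two draws to form a z-score")
    cued_series = np.asarray(cued_series, dtype=float)
    mu = dist.draws.mean(axis=0)
    sd = dist.draws.std(axis=0, ddof=1)
    bad = sd == 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} time points with zero sub-sample spread flagged NaN",
            stacklevel=2,
        )
    z = np.full(cued_series.shape, np.nan)
    np.divide(cued_series - mu, sd, out=z, where=~bad)
    return z


def group_inference(
    z: np.ndarray,
    times: np.ndarray | None = None,
    n_boot: int = 10000,
    n_perm: int = 10000,
    seed: int = 0,
) -> GroupZResult:
    """Group-level test of per-participant z series against zero.

    Per time point: a two-sided sign-flip permutation p-value for the mean z,
    and a 95% percentile-bootstrap confidence interval of the mean. No
    correction across time points is applied (uncorrected convention).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim != 2 or z.shape[0] < 2:
        raise DataError("z must be participants x time points with >= 2 participants")
    ss = np.random.SeedSequence(seed)
    perm_rng, boot_rng = [np.random.default_rng(s) for s in ss.spawn(2)]
    p = sign_flip_pvalues(z, n_perm=n_perm, seed=perm_rng)
    lo, hi = bootstrap_ci_mean(z, n_boot=n_boot, seed=boot_rng)
    if times is None:
        times = np.arange(z.shape[1], dtype=float)
    return GroupZResult(
        mean_z=z.mean(axis=0),
        ci_low=lo,
        ci_high=hi,
        p=p,
        times=np.asarray(times, dtype=float),
    )
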