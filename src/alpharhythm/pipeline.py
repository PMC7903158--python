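"""End-to-end orchestration: simulate -> preprocess -> analyze -> report.

``run_full`` executes the complete sensor-level analysis on a simulated (or
loaded) cohort and assembles a JSON-serializable results report with

* behavioral means and permutation tests (adjusted-logit accuracy, 1/RT
  response speed, linear trend over probed positions);
* pre-stimulus topographic alpha lateralization and its hemisphere contrast;
* 0.8-Hz rhythm amplitudes/phases of ITPC and of time-resolved alpha
  lateralization per temporal-cue condition, with Rayleigh, paired Hotelling,
  and sign-flip permutation tests, plus the ITPC-to-lateralization lag;
* the cued vs uncued and cued vs neutral sub-epoch z-series with bootstrap
  confidence intervals and per-time-point permutation p-values.

Every random stage draws from a stream derived deterministically from the
master seed, so a rerun with the same configuration reproduces the report
except for the wall-clock timestamp.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import design, lateralization, preprocess, rhythm, stats, subepoch, timefreq
from .config import AnalysisConfig
from .errors import DataError
from .io import ParticipantData
from .simulate import (
    make_sensor_layout,
    make_trial_schedule,
    participant_rng,
    simulate_behavior,
    simulate_meg,
    validity_class,
)

logger = logging.getLogger(__name__)

__all__ = ["ResultsReport", "simulate_cohort", "analyze_participant", "run_full"]

CLASSES = ("valid", "invalid", "neutral")


@dataclass
class ResultsReport:
    """Nested, JSON-serializable analysis results."""

    sections: dict

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.sections, indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "ResultsReport":
        return cls(sections=json.loads(Path(path).read_text()))

    def __getitem__(self, key):
        return self.sections[key]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def simulate_cohort(config: AnalysisConfig) -> list[ParticipantData]:
    """Simulate ``config.n_participants`` independent participants.

    Each participant gets one pseudo-random stream seeded from
    (master seed, participant id), so cohorts are reproducible and any
    participant can be regenerated in isolation.
    """
    layout = make_sensor_layout(*config.layout_counts)
    out = []
    for pid in range(config.n_participants):
        rng = participant_rng(config.seed, pid)
        schedule = make_trial_schedule(config.n_trials, seed=rng)
        behavior = simulate_behavior(schedule, config.generator, rng=rng)
        recording = simulate_meg(schedule, layout, config.generator, rng=rng)
        out.append(ParticipantData(recording=recording, behavior=behavior))
    return out


def _behavior_measures(part: ParticipantData, config: AnalysisConfig) -> dict:
    schedule = part.recording.schedule
    merged = schedule.merge(part.behavior, on="trial_id")
    merged["class"] = validity_class(merged).to_numpy()
    pc = {}
    speed = {}
    for cls_ in CLASSES:
        cell = merged[merged["class"] == cls_]
        pc[cls_] = float(cell["correct"].mean())
        speeds = stats.response_speed(cell["rt"].to_numpy(), cutoff=config.rt_cutoff_s)
        speed[cls_] = float(speeds.mean()) if speeds.size else np.nan
    pc_by_position = [
        float(merged.loc[merged["probed_position"] == pos, "correct"].mean())
        for pos in range(1, design.N_POSITIONS + 1)
    ]
    return {"pc": pc, "speed": speed, "pc_by_position": pc_by_position}


def analyze_participant(
    part: ParticipantData, config: AnalysisConfig, subsample_seed: int = 0
) -> dict:
    """Run the full sensor-level analysis for one participant.

    Returns per-participant measures consumed by the group stage; heavy
    intermediates (time-frequency coefficients) are not retained.
    """
    rec = part.recording
    layout = rec.layout
    epochs = preprocess.EpochSet.from_recording(rec)
    epochs = preprocess.bandpass_epochs(
        epochs, config.highpass_hz, config.effective_lowpass(epochs.sfreq)
    )
    if config.resample_hz < epochs.sfreq:
        epochs = preprocess.downsample(epochs, config.resample_hz)
    epochs = preprocess.reject_epochs(epochs, config.reject_threshold)
    retained = rec.schedule.set_index("trial_id").loc[epochs.trial_ids].reset_index()

    tfd = timefreq.stft_decompose(
        epochs.data,
        epochs.sfreq,
        epochs.times,
        freqs=config.tfr_freqs,
        win_len=config.tfr_win_s,
        step=config.tfr_step_s,
        pad_to=config.tfr_pad_s,
        channel_names=epochs.channel_names,
    )

    cond_masks = {
        (cue, side): (
            (retained["cue_type"] == cue) & (retained["attended_side"] == side)
        ).to_numpy()
        for cue in design.CUE_TYPES
        for side in design.SIDES
    }
    for (cue, side), mask in cond_masks.items():
        if mask.sum() < 2:
            raise DataError(f"condition ({cue}, {side}) has fewer than 2 retained trials")

    def _subset(mask):
        return timefreq.TFDecomposition(
            coeffs=tfd.coeffs[mask],
            freqs=tfd.freqs,
            times=tfd.times,
            channel_names=tfd.channel_names,
        )

    itpc_courses = {}
    power_maps = {}
    for (cue, side), mask in cond_masks.items():
        sub = _subset(mask)
        pmap = timefreq.combine_pairs(timefreq.compute_power(sub), layout)
        imap = timefreq.combine_pairs(timefreq.compute_itpc(sub), layout)
        power_maps[(cue, side)] = pmap
        fsel = (imap.freqs >= config.itpc_band[0]) & (imap.freqs <= config.itpc_band[1])
        itpc_courses[(cue, side)] = imap.itpc[:, fsel, :].mean(axis=(0, 1))

    measures: dict = {"n_retained": int(epochs.n_trials)}
    measures["behavior"] = _behavior_measures(part, config)

    # pre-stimulus topographic lateralization, hemisphere means per cue type
    prestim = {}
    for cue in design.CUE_TYPES:
        topo = lateralization.topographic_lateralization(
            power_maps[(cue, "left")],
            power_maps[(cue, "right")],
            band=config.alpha_band,
            window=config.prestim_window,
        )
        prestim[cue] = {
            "left_mean": float(np.nanmean(topo[layout.hemisphere_mask("left")])),
            "right_mean": float(np.nanmean(topo[layout.hemisphere_mask("right")])),
        }
    measures["prestim"] = prestim

    # rhythm spectra of ITPC and time-resolved lateralization per cue type
    spectra = {"itpc": {}, "lateralization": {}}
    for cue in design.CUE_TYPES:
        itpc_course = np.mean(
            [itpc_courses[(cue, side)] for side in design.SIDES], axis=0
        )
        spectra["itpc"][cue] = rhythm.rhythm_spectrum(
            itpc_course, tfd.times, window=config.rhythm_window,
            target_df=config.target_df,
        )
        lat_sides = []
        for side in design.SIDES:
            ipsi, contra = lateralization.split_hemispheres(
                power_maps[(cue, side)], layout, side, band=config.alpha_band
            )
            lat_sides.append(
                lateralization.timeresolved_lateralization(ipsi, contra).values
            )
        spectra["lateralization"][cue] = rhythm.rhythm_spectrum(
            np.mean(lat_sides, axis=0), tfd.times, window=config.rhythm_window,
            target_df=config.target_df,
        )
    measures["spectra"] = spectra

    # sub-epoch analysis on per-trial alpha power
    trial_power = timefreq.trial_alpha_power(tfd, layout, band=config.alpha_band)
    hemi, rel_times, table = subepoch.subepoch_hemi_power(
        trial_power, tfd.times, layout, retained,
        positions=config.positions, window=config.subepoch_window,
    )
    cued = subepoch.cued_lateralization(hemi, table)
    sub_rng = np.random.default_rng(np.random.SeedSequence([subsample_seed, 7]))
    z = {}
    envelopes = {}
    for label in ("uncued", "neutral"):
        dist = subepoch.subsampled_lateralization(
            hemi, table, label, n_draws=config.n_subsample_draws, seed=sub_rng,
            times=rel_times,
        )
        z[label] = subepoch.zscore_contrast(cued, dist)
        envelopes[label] = {
            "p2_5": np.percentile(dist.draws, 2.5, axis=0),
            "p97_5": np.percentile(dist.draws, 97.5, axis=0),
        }
    measures["subepoch"] = {
        "times": rel_times,
        "cued_series": cued,
        "z": z,
        "envelopes": envelopes,
    }
    return measures


def _pairwise_behavior_tests(values: dict[str, np.ndarray], transform, n_perm, seed) -> dict:
    pairs = [("valid", "invalid"), ("valid", "neutral"), ("invalid", "neutral")]
    out = {}
    for i, (a, b) in enumerate(pairs):
        t, p = stats.perm_ttest_paired(
            transform(values[a]), transform(values[b]), n_perm=n_perm, seed=seed + i
        )
        out[f"{a}_vs_{b}"] = {"t": t, "p": p, "n_perm": n_perm, "seed": seed + i}
    return out


def _wrap_deg(deg: float) -> float:
    return float(deg % 360.0)


def run_full(
    config: AnalysisConfig,
    participants: list[ParticipantData] | None = None,
    return_measures: bool = False,
):
    """Execute the full pipeline and assemble the results report.

    ``participants`` defaults to a freshly simulated cohort. With
    ``return_measures=True`` the per-participant measures are returned
    alongside the report.
    """
    if participants is None:
        participants = simulate_cohort(config)
    n = len(participants)
    if n < 2:
        raise DataError("group analysis requires at least two participants")
    seed = int(config.seed)

    measures = []
    for pid, part in enumerate(participants):
        logger.info("analyzing participant %d/%d", pid + 1, n)
        measures.append(
            analyze_participant(part, config, subsample_seed=seed * 100003 + pid)
        )

    report: dict = {
        "provenance": {
            "seed": seed,
            "n_participants": n,
            "n_retained": [m["n_retained"] for m in measures],
            "config": _jsonable(config.to_dict()),
        }
    }

    # ---- behavior
    pc = {c: np.array([m["behavior"]["pc"][c] for m in measures]) for c in CLASSES}
    speed = {c: np.array([m["behavior"]["speed"][c] for m in measures]) for c in CLASSES}
    pc_pos = np.array([m["behavior"]["pc_by_position"] for m in measures])
    trend_slope, trend_p = stats.linear_trend_test(
        stats.logit_adj(np.clip(pc_pos, 0.0, 1.0)), n_perm=config.n_perm, seed=seed + 11
    )
    report["behavior"] = {
        "mean_pc": {c: float(pc[c].mean()) for c in CLASSES},
        "mean_speed": {c: float(np.nanmean(speed[c])) for c in CLASSES},
        "pc_tests": _pairwise_behavior_tests(
            pc, stats.logit_adj, config.n_perm, seed + 20
        ),
        "speed_tests": _pairwise_behavior_tests(
            speed, lambda x: x, config.n_perm, seed + 30
        ),
        "position_trend": {
            "mean_slope": trend_slope, "p": trend_p, "n_perm": config.n_perm,
        },
    }

    # ---- pre-stimulus lateralization
    prestim = {}
    hemi_diff = {}
    for cue in design.CUE_TYPES:
        left = np.array([m["prestim"][cue]["left_mean"] for m in measures])
        right = np.array([m["prestim"][cue]["right_mean"] for m in measures])
        t, p = stats.perm_ttest_paired(left, right, n_perm=config.n_perm, seed=seed + 41)
        hemi_diff[cue] = left - right
        prestim[cue] = {
            "left_mean": float(left.mean()),
            "right_mean": float(right.mean()),
            "hemisphere_contrast": {"t": t, "p": p, "n_perm": config.n_perm},
        }
    t, p = stats.perm_ttest_paired(
        hemi_diff["instructive"], hemi_diff["neutral"],
        n_perm=config.n_perm, seed=seed + 42,
    )
    prestim["instructive_vs_neutral"] = {"t": t, "p": p, "n_perm": config.n_perm}
    report["prestim_lateralization"] = prestim

    # ---- rhythm spectra at the stimulus rate
    band = config.stim_rate_band
    rhythm_section = {}
    phases = {}
    for kind in ("itpc", "lateralization"):
        sect = {}
        amps = {}
        for cue in design.CUE_TYPES:
            specs = [m["spectra"][kind][cue] for m in measures]
            amps[cue] = np.array([rhythm.band_amplitude(s, band) for s in specs])
            angles, resultant = rhythm.phase_angles_across_subjects(specs, band)
            phases[(kind, cue)] = angles
            z, p_ray = stats.rayleigh_test(angles)
            sect[cue] = {
                "amplitude_mean": float(amps[cue].mean()),
                "phase_resultant_length": resultant,
                "rayleigh": {"z": z, "p": p_ray},
            }
        t, p = stats.perm_ttest_paired(
            amps["instructive"], amps["neutral"], n_perm=config.n_perm,
            seed=seed + (51 if kind == "itpc" else 52),
        )
        sect["amplitude_instructive_vs_neutral"] = {
            "t": t, "p": p, "n_perm": config.n_perm,
        }
        if n >= 3:
            F, p_hot = stats.hotelling_paired_circular(
                phases[(kind, "instructive")], phases[(kind, "neutral")]
            )
            sect["phase_instructive_vs_neutral"] = {"F": F, "p": p_hot}
        else:
            sect["phase_instructive_vs_neutral"] = {
                "F": None, "p": None, "note": "requires >= 3 participants",
            }
        rhythm_section[kind] = sect

    # lag of the lateralization rhythm behind the ITPC rhythm, per participant
    lag_angles = []
    for kind_pair in range(n):
        d = 0.0
        for cue in design.CUE_TYPES:
            d_cue = (
                phases[("itpc", cue)][kind_pair]
                - phases[("lateralization", cue)][kind_pair]
            )
            d += d_cue / len(design.CUE_TYPES)
        lag_angles.append(d)
    mean_lag_angle = stats.circ_mean(np.asarray(lag_angles))
    lag_deg = _wrap_deg(np.degrees(mean_lag_angle))
    rhythm_section["itpc_to_lateralization_lag"] = {
        "phase_deg": lag_deg,
        "lag_s": rhythm.phase_to_lag(lag_deg, design.STIM_RATE_HZ),
    }
    report["rhythm"] = rhythm_section

    # ---- sub-epoch contrasts
    sub_times = measures[0]["subepoch"]["times"]
    sub_section = {"times": sub_times}
    for label in ("uncued", "neutral"):
        zmat = np.stack([m["subepoch"]["z"][label] for m in measures])
        group = subepoch.group_inference(
            zmat, times=sub_times, n_boot=config.n_bootstrap,
            n_perm=config.n_perm, seed=seed + (61 if label == "uncued" else 62),
        )
        sub_section[f"cued_vs_{label}"] = {
            "mean_z": group.mean_z,
            "ci_low": group.ci_low,
            "ci_high": group.ci_high,
            "p": group.p,
            "n_perm": config.n_perm,
            "n_boot": config.n_bootstrap,
        }
    sub_section["grand_average_cued"] = np.mean(
        [m["subepoch"]["cued_series"] for m in measures], axis=0
    )
    for label in ("uncued", "neutral"):
        sub_section[f"envelope_{label}"] = {
            k: np.mean([m["subepoch"]["envelopes"][label][k] for m in measures], axis=0)
            for k in ("p2_5", "p97_5")
        }
    report["subepoch"] = sub_section

    report = _jsonable(report)
    result = ResultsReport(sections=report)
    if return_measures:
        return result, measures
    return result
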