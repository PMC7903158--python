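"""Validated analysis configuration.

Defaults reproduce the canonical study parameters: a 20-participant cohort
of 160 trials each, a 102-position combined-gradiometer layout, a 0.3-180 Hz
band-pass with resampling to 500 Hz and a 3 pT/cm-equivalent rejection
threshold, a 0.5-s Hann window stepped by 0.05 s on a 1-20 Hz grid, the
8-12 Hz alpha and 1-5 Hz ITPC bands, rhythm spectra on 1.5-7.5 s at 0.02-Hz
resolution read out at 0.76-0.84 Hz, sub-epochs from -2 to 3.25 s around
number positions 2-4, and 10,000 sub-sample draws / bootstrap samples /
permutations. Cohort-scale fields (sensor counts, sampling rate, resampling
counts) can be reduced for desk-scale runs without touching the design.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace

import yaml

from . import design
from .errors import ConfigurationError
from .simulate import GeneratorParams

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    # cohort / simulation
    n_participants: int = 20
    n_trials: int = design.N_TRIALS_DEFAULT
    layout_counts: tuple[int, int, int] = (48, 48, 6)  # left, right, midline
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    seed: int = 0
    # preprocessing
    highpass_hz: float = 0.3
    lowpass_hz: float = 180.0
    resample_hz: float = 500.0
    reject_threshold: float = 3e-12  # "3 pT/cm-equivalent" field units
    # time-frequency
    tfr_win_s: float = 0.5
    tfr_step_s: float = 0.05
    tfr_pad_s: float = 1.0
    tfr_freqs: tuple[float, ...] = tuple(float(f) for f in range(1, 21))
    itpc_band: tuple[float, float] = (1.0, 5.0)
    alpha_band: tuple[float, float] = (8.0, 12.0)
    # lateralization / rhythm
    prestim_window: tuple[float, float] = (0.0, 1.5)
    rhythm_window: tuple[float, float] = (1.5, 7.5)
    target_df: float = 0.02
    stim_rate_band: tuple[float, float] = (0.76, 0.84)
    # sub-epoch analysis
    subepoch_window: tuple[float, float] = (-2.0, 3.25)
    positions: tuple[int, ...] = (2, 3, 4)
    n_subsample_draws: int = 10000
    n_bootstrap: int = 10000
    # inference
    n_perm: int = 10000
    alpha_level: float = 0.05
    rt_cutoff_s: float = 3.0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if len(self.layout_counts) != 3 or min(self.layout_counts) < 0:
            raise ConfigurationError("layout_counts must be three counts >= 0")
        for name in ("n_subsample_draws", "n_bootstrap", "n_perm"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not 0 < self.alpha_level < 1:
            raise ConfigurationError("alpha_level must lie in (0, 1)")
        lo, hi = self.itpc_band
        if lo >= hi or self.alpha_band[0] >= self.alpha_band[1]:
            raise ConfigurationError("frequency bands must satisfy lo < hi")
        if self.tfr_win_s <= 0 or self.tfr_step_s <= 0 or self.tfr_pad_s < self.tfr_win_s:
            raise ConfigurationError("invalid moving-window parameters")
        if self.prestim_window[0] >= self.prestim_window[1]:
            raise ConfigurationError("prestim_window must satisfy lo < hi")
        if self.rhythm_window[0] >= self.rhythm_window[1]:
            raise ConfigurationError("rhythm_window must satisfy lo < hi")
        if not set(self.positions) <= set(range(1, design.N_POSITIONS + 1)):
            raise ConfigurationError("positions must be number positions 1..5")
        if self.rt_cutoff_s <= 0:
            raise ConfigurationError("rt_cutoff_s must be > 0")

    # -- preprocessing band actually applied, adapted to the sampling rate
    def effective_lowpass(self, sfreq: float) -> float:
        return min(self.lowpass_hz, 0.4 * sfreq)

    def replace(self, **kwargs) -> "AnalysisConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["generator"] = asdict(self.generator)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        if "generator" in d and isinstance(d["generator"], dict):
            gen = dict(d["generator"])
            if "rt_params" in gen:
                gen["rt_params"] = {
                    k: tuple(v) for k, v in gen["rt_params"].items()
                }
            d["generator"] = GeneratorParams(**gen)
        for key in (
            "layout_counts", "tfr_freqs", "itpc_band", "alpha_band",
            "prestim_window", "rhythm_window", "stim_rate_band",
            "subepoch_window", "positions",
        ):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)
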