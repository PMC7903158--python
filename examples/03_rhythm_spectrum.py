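"""Rhythm spectrum of the time-resolved lateralization index.

The index time course over the number-presentation window (1.5-7.5 s) is
Fourier-analyzed at 0.02-Hz resolution and read out at the 0.8-Hz stimulus
rate (0.76-0.84 Hz band). Instructive cues plant a 2x deeper modulation than
neutral ones.
"""

import numpy as np

import alpharhythm as ar
from alpharhythm.lateralization import split_hemispheres, timeresolved_lateralization
from alpharhythm.timefreq import combine_pairs, compute_power

schedule = ar.make_trial_schedule(160, seed=2)
layout = ar.make_sensor_layout(4, 4, 0)
params = ar.GeneratorParams(sampling_rate=100.0, seed=2)
rec = ar.simulate_meg(schedule, layout, params)
tfd = ar.stft_decompose(
    rec.epochs, 100.0, rec.time_axis, freqs=(8, 9, 10, 11, 12),
    channel_names=layout.channel_names,
)

for cue in ("instructive", "neutral"):
    lat_sides = []
    for side in ("left", "right"):
        mask = (
            (schedule["cue_type"] == cue) & (schedule["attended_side"] == side)
        ).to_numpy()
        sub = ar.TFDecomposition(
            coeffs=tfd.coeffs[mask], freqs=tfd.freqs, times=tfd.times,
            channel_names=tfd.channel_names,
        )
        pmap = combine_pairs(compute_power(sub), layout)
        ipsi, contra = split_hemispheres(pmap, layout, side)
        lat_sides.append(timeresolved_lateralization(ipsi, contra).values)
    spec = ar.rhythm_spectrum(np.mean(lat_sides, axis=0), tfd.times)
    amp = ar.band_amplitude(spec)
    phase = ar.band_phase(spec)
    print(f"{cue:12s} 0.8-Hz amplitude = {amp:.3f}, phase = {np.degrees(phase):7.1f} deg")

print("133 deg at 0.8 Hz corresponds to a lag of",
      round(ar.phase_to_lag(133, 0.8), 2), "s")
# The instructive amplitude is about twice the neutral one, recovering the
# planted modulation depths (0.2 vs 0.1) plus the cued-onset boost.
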