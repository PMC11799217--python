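"""Extract the envelope-onset regressor from speech-like audio.

Builds an amplitude-modulated carrier standing in for a short speech
recording, extracts the broadband Hilbert envelope at the 128/s analysis
rate, converts it to the half-wave-rectified onset signal, and counts
envelope peaks — the quantity whose language difference (more peaks per
second in German than in Chinese speech) motivates stimulus-level checks.
"""

import numpy as np

from cocktailtrf import (
    AudioTrack,
    count_envelope_peaks,
    extract_envelope,
    onset_signal,
    percent_excess,
)

fs = 44100
dur = 10.0
rng = np.random.default_rng(0)
t = np.arange(0, dur, 1 / fs)

# carrier with syllable-like 5 Hz amplitude bursts
bursts = np.clip(np.sin(2 * np.pi * 5.0 * t), 0, None) ** 2
audio = AudioTrack(bursts * rng.normal(size=len(t)), fs, label="target")

env = extract_envelope(audio, analysis_rate=128.0)
onsets = onset_signal(env)
stats = count_envelope_peaks(onsets)

print(f"envelope samples: {len(env.values)} at {env.rate:.0f}/s")
print(f"envelope peaks: {stats.count} in {stats.duration:.1f} s "
      f"-> {stats.rate_per_s:.1f}/s")
print(f"published stimulus counts 11169 vs 10199 -> "
      f"{percent_excess(11169, 10199):.1f}% more onsets")
# The peak rate tracks the 5 Hz burst rate; the percent-excess line applies
# the same count arithmetic to the published German/Chinese onset totals.
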