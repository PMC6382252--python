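"""The auditory front-end: gammatone filterbank cochleagram of a tone.

A 160 ms pure tone at a channel center frequency is passed through the
32-channel ERB-spaced gammatone filterbank (1-22.05 kHz, 4th order), windowed
RMS energies (20 ms window, 10 ms step) and log compression, producing the
32 x 15 cochleagram that the generative models consume.
"""

import numpy as np

from maxcause.cochleagram import FilterbankConfig, FrameConfig, waveform_to_cochleagram
from maxcause.synth import synth_waveform

fb = FilterbankConfig()
fr = FrameConfig()
cf = fb.center_frequencies()
k = 10
w = synth_waveform([{"kind": "tone", "freq": float(cf[k])}], 0.160, 44100.0, seed=0)
c = waveform_to_cochleagram(w, fb, fr)

print(f"channels: {len(c.center_freqs)}  ({c.center_freqs[0]:.0f} - {c.center_freqs[-1]:.0f} Hz)")
print(f"frames:   {len(c.frame_times)}  (shape {c.values.shape}, flattened dim {c.values.size})")
peak = int(np.argmax(c.values.sum(axis=1)))
print(f"tone frequency {cf[k]:.0f} Hz -> most energetic channel {peak} (center {cf[peak]:.0f} Hz)")
print(
    "\nA tone placed at a channel center frequency lands its energy in that\n"
    "channel; the 32 x 15 = 480-dimensional flattened cochleagram is the\n"
    "observed vector y of the generative models."
)
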