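"""Generate a synthetic offline acquisition session and extract features.

Builds the standard offline protocol (each of six motions held 4 s with
3 s rests, repeated four times, 1 kHz sampling, six EMG channels plus one
MMG channel), then segments it with 150 ms / 100 ms sliding windows and
computes the four time-domain features per channel.
"""

import numpy as np

import myolock as ml

params = ml.GeneratorParams(seed=1)
recording = ml.generate_session(ml.offline_protocol(), params)
print(f"session: {recording.duration:.0f} s, {recording.n_channels} EMG channels "
      f"at {recording.sampling_rate:.0f} Hz")

fm = ml.per_class_feature_matrix(recording)
classes, counts = np.unique(fm.labels, return_counts=True)
print("windows per class:", dict(zip(classes.tolist(), counts.tolist())))
print(f"feature matrix: {fm.values.shape[0]} windows x {fm.values.shape[1]} features")
print("first columns:", ", ".join(fm.columns[:8]), "...")

# Each motion class contributes 16 s of contraction -> 159 windows; the 24
# columns are MAV, ZC, WL, SSC stacked channel-major over the 6 channels.
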