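"""Segment a corpus into 6 s respiratory cycles, split it, and extract the
two feature representations: normalized log-mel spectrograms (the VAE
input) and 13x130 MFCC matrices (the classifier input).
"""

import tempfile
from pathlib import Path

from respaug import features as ft
from respaug import io as ricio
from respaug import preprocess as pp
from respaug import synth

out = Path(tempfile.mkdtemp(prefix="respaug_prep_"))
counts = {c: 5 for c in ricio.CLASS_LABELS}
synth.generate_corpus(synth.SynthConfig(cycles_per_class=counts, seed=3),
                      out)

recordings = ricio.load_corpus(out)
segments = pp.segment_corpus(recordings)
split = pp.stratified_split(segments, fraction=0.7, seed=0)
print(f"{len(segments)} segments kept "
      f"({sum(len(r.cycles) for r in recordings) - len(segments)} cycles "
      ">6 s discarded); train/test = "
      f"{len(split.train)}/{len(split.test)}")

# mel normalization is fitted on the training segments only (no leakage)
params = ft.fit_normalization(split.train, ft.MelSpecParams())
spec = ft.mel_spectrogram(split.train[0], params)
print(f"mel spectrogram: {spec.values.shape[0]} mel bands x "
      f"{spec.values.shape[1]} frames, values in "
      f"[{spec.values.min():.2f}, {spec.values.max():.2f}]")

m = ft.mfcc(split.train[0])
print(f"MFCC matrix: {m.shape} (13 cepstral coefficients x 130 frames)")
print(f"39-d summary (mean/std/delta per coefficient): "
      f"{ft.summary39(m).shape}")
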