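"""Train a small MLP-VAE on one minority class and generate new
spectrograms, then invert one to audio with Griffin-Lim.

Uses a reduced spectrogram resolution (64x64 average-pooled from 128x256)
so the whole example runs in well under a minute.
"""

import tempfile
from pathlib import Path

import numpy as np

from respaug import features as ft
from respaug import io as ricio
from respaug import preprocess as pp
from respaug import synth
from respaug import vae as vm

out = Path(tempfile.mkdtemp(prefix="respaug_vae_"))
counts = {"URTI": 12, "COPD": 2}
profiles = {k: synth.DEFAULT_PROFILES[k] for k in counts}
synth.generate_corpus(
    synth.SynthConfig(cycles_per_class=counts, seed=5, profiles=profiles),
    out,
)
segments = [s for s in pp.segment_corpus(ricio.load_corpus(out))
            if s.label == "URTI"]
params = ft.fit_normalization(segments, ft.MelSpecParams())
specs = [ft.mel_spectrogram(s, params) for s in segments]

config = vm.VAEConfig(variant="mlp", pool=(2, 4), intermediate_dim=128,
                      epochs=40, batch_size=8, seed=0)
trained = vm.train_vae(vm.build_vae(config), specs, config)
print(f"trained MLP-VAE on {len(specs)} URTI spectrograms; "
      f"negative ELBO {trained.loss_history[0]:.1f} -> "
      f"{trained.loss_history[-1]:.1f} over {config.epochs} epochs")

samples = vm.generate_samples(trained, 5, rng=np.random.default_rng(0))
print(f"generated {len(samples)} spectrograms of shape "
      f"{samples[0].values.shape}, values in "
      f"[{samples[0].values.min():.2f}, {samples[0].values.max():.2f}]")

wav = ft.invert_mel(samples[0], n_iter=8)
rms_db = 20 * np.log10(np.sqrt((wav ** 2).mean()) + 1e-12)
print(f"Griffin-Lim inversion: {len(wav)} samples (6 s at 22050 Hz), "
      f"RMS {rms_db:.1f} dBFS")
print("its MFCC matrix for a classifier:", ft.mfcc(wav).shape)
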