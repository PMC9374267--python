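"""Run the full augmentation experiment end to end at micro scale.

Simulates an imbalanced corpus, trains the three VAE variants, generates
and inverts synthetic audio, and compares two classifiers on the
imbalanced vs augmented training sets.  Takes a minute or two; the full
desk preset (`respaug run-all --preset desk --seed 1 --out-dir ...`)
trains all five classifiers and takes ~15 minutes on one CPU.
"""

import json
import tempfile

from respaug.pipeline import ExperimentConfig, run_experiment

config = ExperimentConfig(
    out_dir=tempfile.mkdtemp(prefix="respaug_micro_"),
    preset="desk",
    seed=11,
    minority_cycles=5,
    vae_epochs=5,
    clf_epochs=3,
    n_trials=2,
    n_generate_per_class=10,
    archs=("mlp", "lstm"),
)
report = run_experiment(config)

print("\nmean FAD of generated audio vs real, per VAE variant:")
print(json.dumps(report["generative"]["fad_mean"], indent=1))
print("\nmean minority-class F1 per (training set | classifier):")
print(json.dumps(report["classification"]["minority_f1"], indent=1))
print("\nHigher minority F1 on the augmented rows than the imbalanced "
      "rows is the effect the study measures (at this micro scale the "
      "numbers are noisy; use the desk preset for a faithful run).")
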