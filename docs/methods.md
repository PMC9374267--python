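# Methods

`respaug` studies a class-imbalance problem in respiratory-sound
classification: corpora of annotated lung sounds are dominated by one
diagnosis (COPD, ~82% of respiratory cycles), and multi-class deep
classifiers trained on such data collapse onto the majority class. The
package implements, end to end, the remedy of augmenting the minority
classes with samples drawn from variational autoencoders trained on
mel spectrograms, and the measurement of what that augmentation does to
five classifiers.

## Pipeline

1. **Input.** ICBHI-format data: one mono WAV per recording, a
   tab-separated annotation file giving respiratory-cycle boundaries and
   crackle/wheeze flags, and a patient-diagnosis CSV. All audio is read as
   float in [-1, 1], downmixed to mono, and resampled to 22 050 Hz.
2. **Preprocessing.** Each recording is sliced at its annotated cycle
   boundaries. Cycles longer than 6 s are discarded (exactly 6 s is kept);
   shorter ones are padded with trailing silence to exactly 132 300
   samples. Segments are split 70/30 per class (shuffled with a seed;
   `floor(n·0.7)` to train). A recording-level split mode is available so
   cycles of one recording never straddle the split; the default is
   segment-level (the class-wise split convention).
3. **Spectrogram front end.** Hann STFT with `n_fft` 2048, hop 512,
   center padding (259 frames for 6 s), a 128-band triangular mel
   filterbank on the HTK mel scale, `log(max(power, 1e-10))`, then min-max
   normalization to [0, 1] using dataset-level bounds fitted **on the VAE
   training segments only** (the sigmoid decoders force a [0, 1] target;
   fitting the bounds on the training side avoids leakage). The trailing
   three frames are trimmed to 256 so the 128×256 grid is divisible by 8,
   which the stride-2 convolutional stacks require.
4. **Generative models.** Three VAEs with 2-dimensional latent spaces:
   an MLP VAE (two ReLU hidden layers of 512 per side, Adam), a
   convolutional VAE (conv 16→32, kernel 3, stride 2; dense bottleneck;
   three stride-2 transposed convolutions 32→16→1; RMSprop), and a
   conditional VAE (the convolutional topology trained on all six
   minority classes jointly, with the one-hot label broadcast as constant
   channels at the encoder input and concatenated to the latent code at
   the decoder). The training objective is the negative ELBO: a
   sum-over-pixels squared reconstruction error plus β times the KL
   divergence of the diagonal-Gaussian posterior from N(0, I), with β = 1.
   The sum (rather than mean) over pixels keeps the KL term from being
   negligible at 128×256 resolution. Unconditional models are instantiated
   per minority class and refuse data from any other class; none of them
   ever sees a test segment.
5. **Generation.** Latent vectors are drawn from N(0, I) (plus the class
   label for the conditional model) and decoded to spectrograms. Each
   minority class is topped up to the majority-class training count, so
   the augmented training sets are balanced. Spectrograms are inverted to
   audio by de-normalizing, exponentiating, applying the mel-filterbank
   pseudo-inverse (clipped at zero), and Griffin-Lim phase estimation.
6. **Classifiers.** Five architectures consume 13×130 MFCC matrices
   (13 orthonormal-DCT coefficients of 128-band log-mel energies; hop
   1024 gives exactly 130 frames for 6 s): an MLP
   (512/512/512/1024/512/512/512 with per-layer dropout 10-40%), a CNN
   (two conv+maxpool stages and dense 64/128/128/64), a two-layer LSTM
   (64, 128 units; dense 64/256/128), and two convolutional-backbone
   models in the ResNet style (stride-2 stem, residual blocks, dense
   256/128/64/512/512/512 head) and the EfficientNet style (five stride-2
   stages to a (1, 5, 1280) map — flattened width 6400 — then dense
   256/128/64). The backbones are randomly initialised, scaled-down
   analogues of their namesakes; no pretrained weights are used, so their
   transfer-learning behaviour is not reproduced. All classifiers train
   with categorical cross-entropy, Adam, learning rate 1e-4, softmax over
   the 7 classes, and standardized inputs (per-coefficient mean/std fitted
   on the training set). Each (classifier, training set) pair is trained
   three times with seeds `seed+trial`.
7. **Evaluation.** Generative quality: Fréchet Audio Distance per class
   (‖μ_r−μ_g‖² + tr(Σ_r+Σ_g−2(Σ_rΣ_g)^{1/2}), matrix square root via
   eigendecomposition with negative eigenvalues clipped at −1e−8); a
   white-noise FAD baseline; normalized (Pearson, lag-0)
   cross-correlation with the max-over-real protocol (sample 50 per side,
   report mean ± std of each synthetic sample's maximum); DTW-aligned mel
   cepstral distortion `(10√2/ln10)·mean_t‖C_t−Ĉ_t‖` over the aligned
   path, c0 excluded by default. Classification: one-vs-rest
   precision/recall/specificity/F1 from the 7×7 confusion matrix
   (zero-denominator metrics are 0 and flagged), macro mean ± population
   std over classes × trials, and a two-way ANOVA with replication
   (training sets × classifiers; replicates are the per-class metric
   values per trial, 7×3 = 21 per cell, so the error df for the 4×5
   design is 400 and the 5% critical F for the training-set factor is
   2.63).

## The synthetic corpus

Everything above is testable offline because the package ships a
generator that emulates the statistical structure of an ICBHI-style
corpus rather than any clinical signal:

* **Imbalance**: the ICBHI-like preset gives COPD 5641/6898 ≈ 81.8% of
  cycles; scaled-down presets preserve the ratio.
* **Durations**: log-normal with mode 2.5 s (σ = 0.3625), ~2% of mass
  above 6 s to exercise the discard rule, clipped to [0.6, 9] s.
* **Acoustics**: every cycle contains band-limited breath noise shaped by
  a two-lobe inhale/exhale envelope; wheezes are 1-3 vibrato harmonics
  with fundamentals inside the 250-800 Hz wheeze band; crackles are
  5-15 ms exponentially decaying noise bursts. Classes differ in wheeze
  sub-band, crackle rate, breath band and envelope asymmetry.
* **Within-class heterogeneity**: each recording draws nuisance
  parameters — gain (σ = 4 dB), broadband sensor noise, ±15% band shifts,
  crackle-rate and amplitude scaling — emulating patient, chest-location
  and equipment variation. This matters: without it the classes are so
  clean that a handful of minority segments suffices and imbalance never
  hurts, which would make the augmentation experiment vacuous.

What the generator does **not** emulate: real spectral fine structure of
adventitious sounds, heart/ambient noise, inter-annotator variability, or
patient-level correlation beyond the per-recording nuisance draws. Tests
passing on this corpus show the pipeline's machinery and the direction of
the augmentation effect under controlled imbalance; they are not evidence
about clinical data.

## Problem sizes and presets

The `desk` preset is the package's own laptop-scale configuration: a
corpus of 8 cycles per minority class and 215 COPD cycles (≈263 total,
ratio preserved), spectrograms average-pooled to 64×64 for the VAEs
(2×4 pooling; generated samples are upsampled back), VAE training 40
epochs (batch 16, width 128/64), Griffin-Lim 3 iterations (MFCCs depend
almost entirely on the magnitude spectrum, so few phase iterations
suffice for augmentation), classifier training 10 epochs at learning
rate 1e-3 with batch 64 and reduced widths, 3 trials, and 5-sample
cross-correlation/MCD subsets. The larger step size compensates for the
short schedule; the `paper` preset keeps the full-scale 100 epochs at
1e-4 and full-size networks. A full desk run is a pure function of its
seed.

## Numerical choices

* Log floor `1e-10` before the log of mel power (silence padding produces
  exact zeros).
* Griffin-Lim: the mel pseudo-inverse can produce small negative powers;
  they are clipped at zero before the square root.
* The ISTFT covers `(frames−1)·hop` samples; inverted waveforms are
  zero-padded to exactly 132 300.
* KL divergence is clamped at 0 (exp(x)−1−x rounds negative at subnormal
  x).
* `exp`/`sigmoid` inputs are clipped (±60) against overflow during early
  training.
* Batch normalization treats batch statistics as constants in the
  backward pass — the standard cheap approximation, exact at
  convergence.
* DTW uses the full dynamic-programming table with the symmetric step
  pattern and no band constraint (130-frame matrices are cheap).
* Ties in stratified splitting are resolved by a seeded permutation; the
  train share is `max(floor(n·fraction), 1)` per class.

## Design choices that were genuinely open

* **Mel normalization** is not stated by the method being implemented;
  min-max to [0, 1] is forced by the sigmoid decoders and adopted.
* **MFCC hop** is unstated while the classifier input is printed as
  (13, 130, 1); hop 1024 is the unique power of two that yields 130
  frames at 22 050 Hz.
* **Encoder/decoder stride mismatch** (the conv encoder downsamples ×4,
  the decoder upsamples ×8): reconciled through the dense bottleneck with
  the decoder grid fixed at (frames/8, mels/8, 32).
* **The FAD embedder** defaults to a self-contained statistic (per-band
  log-mel mean and std over 0.96 s windows, 128-d) so the pipeline runs
  offline and deterministically; VGGish-scale FAD values are therefore
  not comparable in magnitude, only in ordering. Alternative embedders
  can be registered behind the same interface.
* **Cross-correlation** is normalized (Pearson at lag 0) although the
  source formula is unnormalized — reported values in [0, 1] imply
  normalization.
* **MCD** excludes c0 by convention; a flag includes it.
* **ANOVA replicate structure** is per-class-per-trial (21 per cell),
  the only layout consistent with a printed critical F of 2.63 at the
  4×5 design; the training-set factor's F is the one reported.
* **Asthma** (a single patient in the source corpus) is dropped before
  splitting; the classifiers are 7-class.

## Known limitations

* The numpy neural-network engine is single-threaded and slow compared
  to GPU frameworks; the `paper` preset is faithful in structure but
  impractical to run at full scale here.
* Backbone classifiers are random-init stand-ins; claims about
  ImageNet transfer do not carry over.
* FAD magnitudes depend on the embedder; only relative comparisons
  (e.g. generated vs white noise, before vs after training) are
  meaningful with the default embedder.
* The conditional VAE at desk scale sees very few samples per class;
  its conditioning signal is correspondingly weak.
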