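"""Synthetic ICBHI-format respiratory-sound corpus generator.

The generator reproduces the statistical structure the analysis pipeline
assumes rather than clinical realism: seven diagnosis classes with COPD
heavily dominant (5641 of 6898 cycles in the ICBHI-like preset, ~81.8%),
respiratory-cycle durations drawn from a log-normal peaking near 2.5 s with
a small tail beyond 6 s, and class-distinct acoustic content built from
three ingredients:

* band-limited breath noise, amplitude-modulated by an inhale/exhale
  envelope (always present),
* tonal wheezes: 1-3 harmonics with vibrato, fundamental inside the
  250-800 Hz wheeze band,
* crackles: exponentially decaying 5-15 ms noise bursts.

Per-class profiles differ in breath-noise band, wheeze sub-band, crackle
rate and envelope shape so that classes are statistically distinguishable
by MFCC features, which is what downstream tests require.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfilt

from .io import CLASS_LABELS, CycleAnnotation, write_annotation, write_diagnosis, write_wav

#: Log-normal duration parameters: mode 2.5 s with ~2% of mass above 6 s.
DURATION_MODE_S = 2.5
DURATION_SIGMA = 0.3625
DURATION_MAX_S = 9.0
DURATION_MIN_S = 0.6

#: ICBHI-like imbalance: majority (COPD) share of all respiratory cycles.
MAJORITY_CYCLE_FRACTION = 5641 / 6898


@dataclass(frozen=True)
class ClassAcousticProfile:
    """Acoustic recipe for one diagnosis class."""

    wheeze_probability: float
    crackle_probability: float
    wheeze_band_hz: tuple[float, float]  # fundamental range, inside 250-800
    n_harmonics: int
    crackle_rate_per_s: float
    breath_band_hz: tuple[float, float]
    envelope_inhale_fraction: float  # asymmetry of the breath envelope
    noise_amp: float = 0.25
    tone_amp: float = 0.5
    crackle_amp: float = 0.6

    def __post_init__(self):
        if not 0 <= self.wheeze_probability <= 1:
            raise ValueError("wheeze_probability must be in [0, 1]")
        if not 0 <= self.crackle_probability <= 1:
            raise ValueError("crackle_probability must be in [0, 1]")


#: Default per-class profiles.  Classes differ in wheeze sub-band (inside
#: 250-800 Hz), crackle rate, breath-noise band and envelope shape, but the
#: profiles deliberately overlap: combined with the per-recording nuisance
#: variation below, within-class variance is large enough that a handful of
#: segments does not characterise a class — the regime in which class
#: imbalance actually hurts a classifier.
DEFAULT_PROFILES: dict[str, ClassAcousticProfile] = {
    "COPD": ClassAcousticProfile(0.30, 0.70, (250, 400), 2, 9.0,
                                 (80, 900), 0.40),
    "Healthy": ClassAcousticProfile(0.0, 0.0, (250, 800), 1, 0.0,
                                    (100, 1100), 0.50),
    "URTI": ClassAcousticProfile(0.60, 0.25, (550, 780), 2, 4.0,
                                 (150, 1200), 0.50),
    "LRTI": ClassAcousticProfile(0.60, 0.35, (280, 420), 3, 5.0,
                                 (100, 900), 0.40),
    "Bronchiectasis": ClassAcousticProfile(0.15, 0.80, (250, 350), 1, 14.0,
                                           (100, 1000), 0.45),
    "Bronchiolitis": ClassAcousticProfile(0.50, 0.50, (420, 620), 2, 10.0,
                                          (200, 1400), 0.55),
    "Pneumonia": ClassAcousticProfile(0.25, 0.70, (350, 520), 1, 6.0,
                                      (150, 1100), 0.50),
}


def perturb_profile(profile: ClassAcousticProfile, rng: np.random.Generator,
                    jitter: float = 0.15) -> ClassAcousticProfile:
    """Per-recording nuisance variation: shifts the wheeze and breath bands,
    scales the crackle rate and amplitudes.  Emulates patient, chest
    location and equipment heterogeneity; wheeze fundamentals stay inside
    the 250-800 Hz band."""
    def scale(lo_hi, s, clamp=None):
        lo, hi = lo_hi[0] * s, lo_hi[1] * s
        if clamp:
            lo = min(max(lo, clamp[0]), clamp[1] - 30)
            hi = min(max(hi, lo + 20), clamp[1])
        return (lo, hi)

    return ClassAcousticProfile(
        wheeze_probability=profile.wheeze_probability,
        crackle_probability=profile.crackle_probability,
        wheeze_band_hz=scale(profile.wheeze_band_hz,
                             rng.uniform(1 - jitter, 1 + jitter),
                             clamp=(250.0, 800.0)),
        n_harmonics=profile.n_harmonics,
        crackle_rate_per_s=profile.crackle_rate_per_s
        * rng.uniform(0.7, 1.4),
        breath_band_hz=scale(profile.breath_band_hz,
                             rng.uniform(1 - jitter, 1 + jitter)),
        envelope_inhale_fraction=float(np.clip(
            profile.envelope_inhale_fraction + rng.uniform(-0.08, 0.08),
            0.2, 0.8)),
        noise_amp=profile.noise_amp * rng.uniform(0.6, 1.5),
        tone_amp=profile.tone_amp * rng.uniform(0.6, 1.4),
        crackle_amp=profile.crackle_amp * rng.uniform(0.6, 1.4),
    )


@dataclass
class SynthConfig:
    """Full description of a synthetic corpus; a pure function of this
    config (including the seed) yields a byte-identical corpus."""

    cycles_per_class: dict[str, int]
    cycles_per_recording: tuple[int, int] = (4, 9)
    sample_rate: int = 22050
    seed: int = 0
    duration_mode_s: float = DURATION_MODE_S
    duration_sigma: float = DURATION_SIGMA
    duration_max_s: float = DURATION_MAX_S
    profiles: dict[str, ClassAcousticProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    equipment: str = "Synth"
    profile_jitter: float = 0.15  # per-recording band/rate variation
    gain_db_sd: float = 4.0  # per-recording gain spread
    sensor_noise_range: tuple[float, float] = (0.02, 0.08)

    def __post_init__(self):
        for label, n in self.cycles_per_class.items():
            if n < 0:
                raise ValueError(f"negative cycle count for {label!r}")
            if label not in self.profiles:
                raise ValueError(f"no acoustic profile for class {label!r}")
        if self.duration_mode_s >= self.duration_max_s:
            raise ValueError("duration mode must be below the maximum")


def icbhi_like_counts(total_cycles: int = 6898) -> dict[str, int]:
    """Per-class cycle counts with the ICBHI-style COPD-dominant imbalance.

    COPD takes ``MAJORITY_CYCLE_FRACTION`` of all cycles; the remainder is
    split evenly over the six minority classes (the source corpus is uneven
    across minorities, but only the majority share drives the experiment).
    """
    copd = round(total_cycles * MAJORITY_CYCLE_FRACTION)
    rest = total_cycles - copd
    minorities = [c for c in CLASS_LABELS if c != "COPD"]
    counts = {"COPD": copd}
    base, extra = divmod(rest, len(minorities))
    for i, label in enumerate(minorities):
        counts[label] = base + (1 if i < extra else 0)
    return counts


def desk_counts(minority: int = 14) -> dict[str, int]:
    """Small ICBHI-like-imbalanced counts for desk-scale runs."""
    rest = 6 * minority
    copd = round(rest * MAJORITY_CYCLE_FRACTION / (1 - MAJORITY_CYCLE_FRACTION))
    counts = {c: minority for c in CLASS_LABELS if c != "COPD"}
    counts["COPD"] = copd
    return counts


def sample_duration(rng: np.random.Generator, config: SynthConfig) -> float:
    mu = np.log(config.duration_mode_s) + config.duration_sigma ** 2
    d = float(rng.lognormal(mean=mu, sigma=config.duration_sigma))
    return float(np.clip(d, DURATION_MIN_S, config.duration_max_s))


def _bandpass(x: np.ndarray, band: tuple[float, float], sr: int) -> np.ndarray:
    nyq = sr / 2
    lo = max(band[0] / nyq, 1e-4)
    hi = min(band[1] / nyq, 0.99)
    sos = butter(4, [lo, hi], btype="bandpass", output="sos")
    return sosfilt(sos, x)


def synth_cycle(profile: ClassAcousticProfile, duration_s: float,
                rng: np.random.Generator, sample_rate: int = 22050,
                wheeze: bool | None = None, crackle: bool | None = None
                ) -> np.ndarray:
    """Synthesize one respiratory cycle; waveform values lie in [-1, 1].

    When ``wheeze``/``crackle`` are None they are drawn from the profile's
    probabilities; passing them explicitly lets the corpus generator keep
    the annotation flags consistent with the audio.
    """
    if not 0.3 <= duration_s <= 10:
        raise ValueError(f"duration {duration_s} s outside [0.3, 10]")
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    if wheeze is None:
        wheeze = rng.random() < profile.wheeze_probability
    if crackle is None:
        crackle = rng.random() < profile.crackle_probability

    # inhale/exhale amplitude envelope: two raised-cosine lobes
    split = profile.envelope_inhale_fraction * duration_s
    env = np.where(
        t < split,
        np.sin(np.pi * t / max(split, 1e-6)) ** 2,
        np.sin(np.pi * (t - split) / max(duration_s - split, 1e-6)) ** 2,
    )
    env = 0.15 + 0.85 * env

    x = np.zeros(n)
    if profile.noise_amp > 0:
        noise = _bandpass(rng.standard_normal(n), profile.breath_band_hz,
                          sample_rate)
        peak = np.max(np.abs(noise))
        if peak > 0:
            noise = noise / peak
        x += profile.noise_amp * env * noise

    if wheeze and profile.tone_amp > 0:
        f0 = rng.uniform(*profile.wheeze_band_hz)
        vibrato = 1.0 + 0.01 * np.sin(2 * np.pi * rng.uniform(4, 7) * t)
        phase = 2 * np.pi * np.cumsum(f0 * vibrato) / sample_rate
        tone = np.zeros(n)
        for h in range(1, profile.n_harmonics + 1):
            tone += np.sin(h * phase + rng.uniform(0, 2 * np.pi)) / h
        x += profile.tone_amp * env * tone / profile.n_harmonics

    if crackle and profile.crackle_amp > 0:
        n_bursts = max(1, rng.poisson(profile.crackle_rate_per_s * duration_s))
        for _ in range(n_bursts):
            width_s = rng.uniform(0.005, 0.015)  # 5-15 ms transient
            m = max(int(width_s * sample_rate), 8)
            start = rng.integers(0, max(n - m, 1))
            decay = np.exp(-np.arange(m) / (m / 4))
            x[start:start + m] += (
                profile.crackle_amp * decay * rng.standard_normal(m)
            )[: n - start]

    peak = np.max(np.abs(x))
    if peak > 0.95:
        x = 0.95 * x / peak
    return x


def generate_corpus(config: SynthConfig, out_dir) -> dict:
    """Write a full ICBHI-format corpus and return its manifest.

    One synthetic patient per recording; cycles are laid back to back so the
    annotation end time of the last cycle equals the recording duration.
    Per-class cycle counts match the config exactly by construction.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    diagnosis: dict[str, str] = {}
    manifest_recs = []
    patient = 101
    lo, hi = config.cycles_per_recording
    for label in sorted(config.cycles_per_class):
        remaining = config.cycles_per_class[label]
        profile = config.profiles[label]
        while remaining > 0:
            n_cycles = min(int(rng.integers(lo, hi + 1)), remaining)
            remaining -= n_cycles
            rec_profile = perturb_profile(profile, rng,
                                          config.profile_jitter)
            gain = 10.0 ** (rng.normal(0.0, config.gain_db_sd) / 20.0)
            sensor = rng.uniform(*config.sensor_noise_range)
            pieces, annotations, cursor = [], [], 0  # cursor in samples
            for _ in range(n_cycles):
                dur = sample_duration(rng, config)
                has_wheeze = rng.random() < rec_profile.wheeze_probability
                has_crackle = rng.random() < rec_profile.crackle_probability
                wav = synth_cycle(rec_profile, dur, rng,
                                  sample_rate=config.sample_rate,
                                  wheeze=has_wheeze, crackle=has_crackle)
                annotations.append(
                    CycleAnnotation(cursor / config.sample_rate,
                                    (cursor + len(wav)) / config.sample_rate,
                                    int(has_crackle), int(has_wheeze))
                )
                pieces.append(wav)
                cursor += len(wav)
            meta_stem = f"{patient}_1b1_Al_sc_{config.equipment}"
            waveform = np.concatenate(pieces)
            # recording-level gain and broadband sensor noise
            waveform = gain * waveform + sensor * rng.standard_normal(
                len(waveform))
            peak = np.max(np.abs(waveform))
            if peak > 0.98:
                waveform = 0.98 * waveform / peak
            write_wav(out_dir / f"{meta_stem}.wav", waveform,
                      config.sample_rate)
            write_annotation(out_dir / f"{meta_stem}.txt", annotations)
            diagnosis[str(patient)] = label
            manifest_recs.append(
                {"stem": meta_stem, "class": label, "n_cycles": n_cycles}
            )
            patient += 1
    write_diagnosis(out_dir / "diagnosis.csv", diagnosis)
    manifest = {
        "seed": config.seed,
        "sample_rate": config.sample_rate,
        "cycles_per_class": dict(sorted(config.cycles_per_class.items())),
        "n_recordings": len(manifest_recs),
        "recordings": manifest_recs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
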