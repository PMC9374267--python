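"""Config-driven orchestration of the full augmentation experiment.

Stages: simulate (or ingest) -> preprocess/split -> feature extraction ->
VAE training (three variants; one model per minority class for the
unconditional variants) -> sample generation and Griffin-Lim inversion ->
generative-quality evaluation (FAD, cross-correlation, DTW-MCD, PCA) ->
classifier training on the imbalanced and three augmented training sets ->
classification evaluation (per-class metrics, macro report, two-way ANOVA).

Each stage writes its artifacts under ``out_dir`` together with a content
hash of the configuration slice it depends on; a rerun with an unchanged
config skips completed stages.  The ``desk`` preset scales everything to
minutes on one CPU: a small ICBHI-like imbalanced corpus, 64x64 pooled
spectrograms, reduced network widths and epochs, and a reduced number of
generated samples.  The ``paper`` preset keeps the full-size settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification_eval as ce
from . import classifiers as clf
from . import features as ft
from . import generative_eval as ge
from . import io as icbhi
from . import preprocess as pp
from . import synth
from . import vae as vae_mod
from .io import CLASS_LABELS, MINORITY_LABELS

log = logging.getLogger(__name__)

VAE_VARIANTS = ("mlp", "cnn", "conditional")
TRAINING_SETS = ("imbalanced", "mlpvae", "cnnvae", "cvae")
_VARIANT_OF_SET = {"mlpvae": "mlp", "cnnvae": "cnn", "cvae": "conditional"}


@dataclass
class ExperimentConfig:
    out_dir: str
    preset: str = "desk"
    seed: int = 0
    data_dir: str | None = None  # None -> simulate a synthetic corpus
    minority_cycles: int = 8  # desk corpus size knob (ICBHI-like imbalance)
    split_fraction: float = 0.7
    split_by_recording: bool = False
    vae_epochs: int | None = None
    clf_epochs: int | None = None
    clf_learning_rate: float | None = None
    n_trials: int = 3
    n_generate_per_class: int | None = None
    griffin_lim_iters: int | None = None
    n_cc_per_class: int | None = None
    archs: tuple[str, ...] = clf.ARCHS

    def __post_init__(self):
        if self.preset not in ("desk", "paper"):
            raise ValueError(f"unknown preset {self.preset!r}")
        d = self.preset == "desk"
        if self.vae_epochs is None:
            self.vae_epochs = 40 if d else 100
        if self.clf_epochs is None:
            self.clf_epochs = 10 if d else 100
        if self.clf_learning_rate is None:
            # desk runs take few optimizer steps, so a larger step size
            # replaces the full-scale schedule of 100 epochs at 1e-4
            self.clf_learning_rate = 1e-3 if d else 1e-4
        # n_generate_per_class None -> balance each minority class up to
        # the majority-class training count, so augmented sets are balanced
        if self.griffin_lim_iters is None:
            self.griffin_lim_iters = 3 if d else 32
        if self.n_cc_per_class is None:
            self.n_cc_per_class = 5 if d else 50

    @property
    def pool(self) -> tuple[int, int]:
        return (2, 4) if self.preset == "desk" else (1, 1)

    def vae_config(self, variant: str, seed: int) -> vae_mod.VAEConfig:
        d = self.preset == "desk"
        return vae_mod.VAEConfig(
            variant=variant,
            intermediate_dim=128 if d else 512,
            bottleneck_dim=64 if d else 128,
            pool=self.pool,
            epochs=self.vae_epochs,
            batch_size=16 if d else 32,
            seed=seed,
        )

    def clf_config(self, arch: str, seed: int) -> clf.ClfConfig:
        return clf.ClfConfig(
            arch=arch,
            preset=self.preset if self.preset in ("desk", "paper") else "desk",
            epochs=self.clf_epochs,
            learning_rate=self.clf_learning_rate,
            batch_size=64 if self.preset == "desk" else 32,
            n_trials=self.n_trials,
            seed=seed,
        )


# -- caching helpers ---------------------------------------------------------

def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class _StageRunner:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.out_dir.mkdir(parents=True, exist_ok=True)

    def run(self, name: str, dep_hash: str, outputs: list[Path], fn):
        marker = self.out_dir / f".{name}.hash"
        if marker.exists() and marker.read_text() == dep_hash and all(
            p.exists() for p in outputs
        ):
            log.info("stage %s: up to date, skipped", name)
            return False
        t0 = time.time()
        fn()
        marker.write_text(dep_hash)
        log.info("stage %s: done in %.1f s", name, time.time() - t0)
        return True


# -- the experiment ----------------------------------------------------------

class Experiment:
    """Holds per-run state; ``run()`` executes all stages in order."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.runner = _StageRunner(self.out)
        self.report: dict = {}

    # stage 1 ---------------------------------------------------------------
    def simulate(self) -> Path:
        cfg = self.config
        if cfg.data_dir is not None:
            return Path(cfg.data_dir)
        corpus_dir = self.out / "corpus"
        counts = synth.desk_counts(cfg.minority_cycles)
        dep = _hash({"counts": counts, "seed": cfg.seed})
        self.runner.run(
            "simulate", dep, [corpus_dir / "manifest.json"],
            lambda: synth.generate_corpus(
                synth.SynthConfig(cycles_per_class=counts, seed=cfg.seed),
                corpus_dir,
            ),
        )
        return corpus_dir

    # stage 2 ---------------------------------------------------------------
    def preprocess(self, corpus_dir: Path) -> pd.DataFrame:
        cfg = self.config
        out_csv = self.out / "split.csv"
        dep = _hash({"corpus": str(corpus_dir), "fraction": cfg.split_fraction,
                     "by_recording": cfg.split_by_recording,
                     "seed": cfg.seed})

        def _run():
            recordings = icbhi.load_corpus(corpus_dir)
            segments = pp.segment_corpus(recordings)
            split = pp.stratified_split(
                segments, cfg.split_fraction, seed=cfg.seed,
                by_recording=cfg.split_by_recording,
            )
            rows = []
            for part, segs in (("train", split.train), ("test", split.test)):
                for s in segs:
                    rows.append({
                        "stem": s.source[0], "cycle": s.source[1],
                        "label": s.label, "split": part,
                        "duration_s": round(s.original_duration_s, 6),
                    })
            pd.DataFrame(rows).to_csv(out_csv, index=False)

        self.runner.run("preprocess", dep, [out_csv], _run)
        df = pd.read_csv(out_csv)
        for part in ("train", "test"):
            sub = df[df.split == part]
            log.info("%s counts: %s", part,
                     dict(sub.label.value_counts()))
        return df

    # stage 3 ---------------------------------------------------------------
    def features(self, corpus_dir: Path, split: pd.DataFrame):
        """Single streaming pass over the corpus: MFCCs and FAD embeddings
        for every kept segment, pooled log-mel matrices for the VAE training
        segments, and a small bank of real waveforms for the
        cross-correlation protocol."""
        cfg = self.config
        out_npz = self.out / "features.npz"
        dep = _hash({"corpus": str(corpus_dir), "pool": cfg.pool,
                     "n_cc": cfg.n_cc_per_class,
                     "split": _hash(split.to_dict("list"))})

        def _run():
            assign = {
                (r.stem, r.cycle): r.split for r in split.itertuples()
            }
            mel_params = ft.MelSpecParams()
            keys, mfccs, embeds = [], [], []
            vae_keys, vae_logmels = [], []
            recordings = icbhi.load_corpus(corpus_dir)
            for rec in recordings:
                if rec.diagnosis == "Asthma":
                    continue
                slices = pp.segment_recording(rec)
                sources = [(rec.meta.stem, i) for i in range(len(slices))]
                for seg in pp.pad_or_discard(slices, sources):
                    part = assign.get(seg.source)
                    if part is None:
                        continue
                    keys.append((seg.source[0], seg.source[1], seg.label,
                                 part))
                    mfccs.append(ft.mfcc(seg).astype(np.float32))
                    embeds.append(
                        ge.embed_audio(seg.waveform).astype(np.float32)
                    )
                    if part == "train" and seg.label in MINORITY_LABELS:
                        vae_keys.append(len(keys) - 1)
                        vae_logmels.append(
                            ft.log_mel_power(seg.waveform, mel_params
                                             ).astype(np.float32)
                        )
            # dataset-level normalization fitted on VAE training set only
            stack = np.stack(vae_logmels)
            norm_min, norm_max = float(stack.min()), float(stack.max())
            if norm_max <= norm_min:
                raise ValueError("degenerate log-mel dynamic range")
            # real waveform bank for the cross-correlation protocol
            rng = np.random.default_rng(cfg.seed + 101)
            train_min = {
                c: [i for i, k in enumerate(keys)
                    if k[3] == "train" and k[2] == c]
                for c in MINORITY_LABELS
            }
            cc_idx = {
                c: sorted(
                    rng.choice(idx, size=min(cfg.n_cc_per_class, len(idx)),
                               replace=False).tolist()
                )
                for c, idx in train_min.items()
            }
            wanted = {i for idx in cc_idx.values() for i in idx}
            cc_waves = {}
            for rec in recordings:
                if rec.diagnosis == "Asthma":
                    continue
                slices = pp.segment_recording(rec)
                sources = [(rec.meta.stem, i) for i in range(len(slices))]
                for seg in pp.pad_or_discard(slices, sources):
                    for i in wanted:
                        if keys[i][:2] == seg.source:
                            cc_waves[i] = seg.waveform.astype(np.float32)
            np.savez_compressed(
                out_npz,
                keys=np.array([
                    [k[0], str(k[1]), k[2], k[3]] for k in keys
                ]),
                mfccs=np.stack(mfccs),
                embeds=np.stack(embeds),
                vae_index=np.array(vae_keys),
                vae_logmels=stack,
                norm=np.array([norm_min, norm_max]),
                cc_index=json.dumps({c: v for c, v in cc_idx.items()}),
                cc_waves_idx=np.array(sorted(cc_waves)),
                cc_waves=np.stack([cc_waves[i] for i in sorted(cc_waves)]),
            )

        self.runner.run("features", dep, [out_npz], _run)
        return np.load(out_npz, allow_pickle=False)

    # stage 4 ---------------------------------------------------------------
    def train_vaes(self, feats) -> dict:
        cfg = self.config
        norm_min, norm_max = feats["norm"]
        mel_params = ft.MelSpecParams(norm_min=float(norm_min),
                                      norm_max=float(norm_max))
        keys = feats["keys"]
        vae_idx = feats["vae_index"]
        logmels = feats["vae_logmels"].astype(np.float64)
        specs_by_class: dict[str, list[ft.MelSpec]] = {}
        for row, lm in zip(vae_idx, logmels):
            label = keys[row][2]
            values = np.clip(
                (lm - norm_min) / (norm_max - norm_min), 0.0, 1.0
            )
            specs_by_class.setdefault(label, []).append(
                ft.MelSpec(values, mel_params, label)
            )

        trained: dict = {}
        for variant in VAE_VARIANTS:
            weights_file = self.out / f"vae_{variant}.npz"
            dep = _hash({
                "variant": variant, "epochs": cfg.vae_epochs,
                "pool": cfg.pool, "seed": cfg.seed, "preset": cfg.preset,
                "n_specs": {c: len(v) for c, v in
                            sorted(specs_by_class.items())},
            })

            def _run(variant=variant, weights_file=weights_file):
                store, histories = {}, {}
                if variant == "conditional":
                    vcfg = cfg.vae_config(variant, cfg.seed + 11)
                    model = vae_mod.build_vae(vcfg)
                    specs = [s for c in MINORITY_LABELS
                             for s in specs_by_class[c]]
                    tv = vae_mod.train_vae(model, specs, vcfg)
                    store["conditional"] = tv.state_dict()
                    histories["conditional"] = tv.loss_history
                else:
                    for ci, label in enumerate(MINORITY_LABELS):
                        vcfg = cfg.vae_config(variant,
                                              cfg.seed + 23 + ci)
                        model = vae_mod.build_vae(vcfg)
                        tv = vae_mod.train_vae(
                            model, specs_by_class[label], vcfg
                        )
                        store[label] = tv.state_dict()
                        histories[label] = tv.loss_history
                np.savez_compressed(
                    weights_file,
                    names=json.dumps({k: len(v) for k, v in store.items()}),
                    histories=json.dumps(histories),
                    **{f"{k}__{i}": arr for k, v in store.items()
                       for i, arr in enumerate(v)},
                )

            self.runner.run(f"train-vae-{variant}", dep, [weights_file], _run)
            trained[variant] = (weights_file, mel_params)
        return trained

    def _load_vae(self, variant: str, label: str | None,
                  weights_file: Path, mel_params) -> vae_mod.TrainedVAE:
        cfg = self.config
        data = np.load(weights_file, allow_pickle=False)
        histories = json.loads(str(data["histories"]))
        if variant == "conditional":
            vcfg = cfg.vae_config(variant, cfg.seed + 11)
            key, hist = "conditional", histories["conditional"]
        else:
            ci = MINORITY_LABELS.index(label)
            vcfg = cfg.vae_config(variant, cfg.seed + 23 + ci)
            key, hist = label, histories[label]
        model = vae_mod.build_vae(vcfg)
        n = json.loads(str(data["names"]))[key]
        model.load_state_dict([data[f"{key}__{i}"] for i in range(n)])
        return vae_mod.TrainedVAE(vcfg, model, hist,
                                  None if variant == "conditional" else label,
                                  mel_params=mel_params)

    # stage 5 ---------------------------------------------------------------
    def generate(self, trained: dict, feats) -> Path:
        """Sample spectrograms, invert with Griffin-Lim, extract MFCCs and
        embeddings of the synthetic audio.

        When ``n_generate_per_class`` is unset, every minority class is
        topped up to the majority-class training count so the augmented
        training sets are balanced."""
        cfg = self.config
        out_npz = self.out / "synthetic.npz"
        if cfg.n_generate_per_class is not None:
            n_generate = cfg.n_generate_per_class
        else:
            keys = feats["keys"]
            n_generate = sum(
                1 for k in keys if k[3] == "train" and k[2] == "COPD"
            )
        dep = _hash({"n": n_generate,
                     "gl": cfg.griffin_lim_iters, "seed": cfg.seed,
                     "preset": cfg.preset, "epochs": cfg.vae_epochs})

        def _run():
            payload = {}
            for vi, variant in enumerate(VAE_VARIANTS):
                weights_file, mel_params = trained[variant]
                for li, label in enumerate(MINORITY_LABELS):
                    tv = self._load_vae(
                        variant,
                        None if variant == "conditional" else label,
                        weights_file, mel_params,
                    )
                    rng = np.random.default_rng(
                        cfg.seed + 1000 + 100 * vi + li
                    )
                    specs = vae_mod.generate_samples(
                        tv, n_generate,
                        class_label=label if variant == "conditional"
                        else None,
                        rng=rng,
                    )
                    mfccs, embeds, waves = [], [], []
                    for i, spec in enumerate(specs):
                        wav = ft.invert_mel(spec, cfg.griffin_lim_iters,
                                            seed=cfg.seed + i)
                        mfccs.append(ft.mfcc(wav).astype(np.float32))
                        embeds.append(
                            ge.embed_audio(wav).astype(np.float32))
                        if i < cfg.n_cc_per_class:
                            waves.append(wav.astype(np.float32))
                    payload[f"{variant}__{label}__mfcc"] = np.stack(mfccs)
                    payload[f"{variant}__{label}__embed"] = np.stack(embeds)
                    payload[f"{variant}__{label}__wave"] = np.stack(waves)
            np.savez_compressed(out_npz, **payload)

        self.runner.run("generate", dep, [out_npz], _run)
        return out_npz

    # stage 6 ---------------------------------------------------------------
    def eval_generative(self, feats, syn_npz: Path) -> dict:
        cfg = self.config
        out_json = self.out / "generative_eval.json"
        dep = _hash({"seed": cfg.seed, "n_cc": cfg.n_cc_per_class,
                     "syn": str(syn_npz), "preset": cfg.preset,
                     "epochs": cfg.vae_epochs})

        def _run():
            from . import plots
            figures = self.out / "figures"
            figures.mkdir(exist_ok=True)
            syn = np.load(syn_npz, allow_pickle=False)
            keys = feats["keys"]
            embeds = feats["embeds"].astype(np.float64)
            mfccs = feats["mfccs"].astype(np.float64)
            cc_index = json.loads(str(feats["cc_index"]))
            cc_pos = {int(i): p for p, i in
                      enumerate(feats["cc_waves_idx"])}
            cc_waves = feats["cc_waves"].astype(np.float64)
            real_train_idx = {
                c: [i for i, k in enumerate(keys)
                    if k[3] == "train" and k[2] == c]
                for c in MINORITY_LABELS
            }
            rng = np.random.default_rng(cfg.seed + 7)
            noise_embeds = {}
            result = {"fad": {}, "fad_mean": {}, "fad_noise": {},
                      "cc_mean": {}, "mcd_mean": {}, "mcd_std": {},
                      "pca_explained_variance": {}}
            for variant in VAE_VARIANTS:
                fads, noise_fads = {}, {}
                cc_real, cc_syn = {}, {}
                mcd_mean, mcd_std = {}, {}
                pca_ev = {}
                for label in MINORITY_LABELS:
                    re = embeds[real_train_idx[label]]
                    se = syn[f"{variant}__{label}__embed"].astype(np.float64)
                    stats_r = ge.EmbeddingStats.from_embeddings(re)
                    stats_s = ge.EmbeddingStats.from_embeddings(se)
                    fads[label] = ge.frechet_distance(stats_r, stats_s)
                    if label not in noise_embeds:
                        noise = rng.uniform(
                            -0.5, 0.5,
                            size=(len(se), pp.SEGMENT_SAMPLES)
                        )
                        noise_embeds[label] = np.stack(
                            [ge.embed_audio(w) for w in noise]
                        )
                    noise_fads[label] = ge.frechet_distance(
                        stats_r,
                        ge.EmbeddingStats.from_embeddings(
                            noise_embeds[label]),
                    )
                    cc_real[label] = [cc_waves[cc_pos[i]]
                                      for i in cc_index[label]]
                    cc_syn[label] = list(
                        syn[f"{variant}__{label}__wave"].astype(np.float64)
                    )
                    # DTW-MCD on MFCC subsets
                    real_m = mfccs[cc_index[label]]
                    syn_m = syn[f"{variant}__{label}__mfcc"][
                        :cfg.n_cc_per_class].astype(np.float64)
                    values = [ge.mcd(rm, sm) for sm in syn_m
                              for rm in real_m]
                    mcd_mean[label] = float(np.mean(values))
                    mcd_std[label] = float(np.std(values))
                    # 2-d PCA of 39-d MFCC summaries, real vs synthetic
                    real_s39 = np.stack([
                        ft.summary39(m)
                        for m in mfccs[real_train_idx[label]]
                    ])
                    syn_s39 = np.stack([
                        ft.summary39(m.astype(np.float64)) for m in
                        syn[f"{variant}__{label}__mfcc"][:200]
                    ])
                    coords, ev = ft.pca_project(
                        np.vstack([real_s39, syn_s39]), n_components=2
                    )
                    pca_ev[label] = [float(v) for v in ev]
                    plots.pca_scatter(
                        coords[:len(real_s39)], coords[len(real_s39):],
                        f"{label} ({variant})",
                        figures / f"pca_{variant}_{label}.png",
                    )
                ccs = ge.cc_matrix(cc_real, cc_syn,
                                   n_per_class=cfg.n_cc_per_class,
                                   rng=np.random.default_rng(cfg.seed + 13))
                result["fad"][variant] = fads
                result["fad_mean"][variant] = ge.mean_fad(fads)
                result["fad_noise"][variant] = noise_fads
                result["cc_mean"][variant] = ccs.mean
                result["mcd_mean"][variant] = mcd_mean
                result["mcd_std"][variant] = mcd_std
                result["pca_explained_variance"][variant] = pca_ev
                plots.cc_heatmap(
                    ccs.mean, figures / f"cc_{variant}.png",
                    title=f"mean max cross-correlation ({variant})",
                )
            plots.fad_bars(result["fad"], figures / "fad.png")
            plots.mcd_bars(result["mcd_mean"], result["mcd_std"],
                           figures / "mcd.png")
            with open(out_json, "w") as fh:
                json.dump(result, fh, indent=1)

        self.runner.run("eval-gen", dep, [out_json], _run)
        with open(out_json) as fh:
            return json.load(fh)

    # stage 7 ---------------------------------------------------------------
    def train_classifiers(self, feats, syn_npz: Path) -> Path:
        cfg = self.config
        out_csv = self.out / "predictions.csv"
        dep = _hash({"archs": cfg.archs, "epochs": cfg.clf_epochs,
                     "lr": cfg.clf_learning_rate, "trials": cfg.n_trials,
                     "seed": cfg.seed, "preset": cfg.preset,
                     "vae_epochs": cfg.vae_epochs,
                     "n_gen": cfg.n_generate_per_class,
                     "syn": str(syn_npz)})

        def _run():
            syn = np.load(syn_npz, allow_pickle=False)
            keys = feats["keys"]
            mfccs = feats["mfccs"].astype(np.float64)
            train_idx = [i for i, k in enumerate(keys) if k[3] == "train"]
            test_idx = [i for i, k in enumerate(keys) if k[3] == "test"]
            real_train = [(mfccs[i], keys[i][2]) for i in train_idx]
            test_m = [mfccs[i] for i in test_idx]
            test_labels = [keys[i][2] for i in test_idx]
            sets = {"imbalanced": real_train}
            for name, variant in _VARIANT_OF_SET.items():
                extra = [
                    (m.astype(np.float64), label)
                    for label in MINORITY_LABELS
                    for m in syn[f"{variant}__{label}__mfcc"]
                ]
                sets[name] = real_train + extra
            rows = []
            for ts_name, train_set in sets.items():
                for arch in cfg.archs:
                    ccfg = cfg.clf_config(arch, cfg.seed + 31)
                    model = clf.train_classifier(train_set, ccfg)
                    for trial in range(cfg.n_trials):
                        probs, pred = clf.predict(model, test_m,
                                                  trial=trial)
                        for i, (t, p) in enumerate(zip(test_labels, pred)):
                            rows.append({
                                "training_set": ts_name, "arch": arch,
                                "trial": trial, "segment": i,
                                "true": t, "predicted": p,
                                **{f"p_{c}": float(probs[i, j])
                                   for j, c in enumerate(CLASS_LABELS)},
                            })
                    log.info("trained %s on %s (%d samples)",
                             arch, ts_name, len(train_set))
            pd.DataFrame(rows).to_csv(out_csv, index=False)

        self.runner.run("train-clf", dep, [out_csv], _run)
        return out_csv

    # stage 8 ---------------------------------------------------------------
    def eval_classifiers(self, pred_csv: Path) -> dict:
        cfg = self.config
        out_json = self.out / "classification_eval.json"
        dep = _hash({"pred": str(pred_csv), "trials": cfg.n_trials,
                     "epochs": cfg.clf_epochs, "seed": cfg.seed})

        def _run():
            df = pd.read_csv(pred_csv)
            per_metric = {m: {} for m in
                          ("precision", "recall", "specificity", "f1")}
            minority_f1 = {}
            per_class_f1 = {}
            for (ts, arch), sub in df.groupby(["training_set", "arch"]):
                values = {m: [] for m in per_metric}
                min_f1, cls_f1 = [], {c: [] for c in MINORITY_LABELS}
                for trial, tsub in sub.groupby("trial"):
                    cm = ce.confusion(tsub["true"], tsub["predicted"])
                    metrics = ce.per_class_metrics(cm)
                    for m in per_metric:
                        values[m].extend(getattr(metrics, m).values())
                    for c in MINORITY_LABELS:
                        min_f1.append(metrics.f1[c])
                        cls_f1[c].append(metrics.f1[c])
                for m in per_metric:
                    mean, std = ce.macro_report(values[m])
                    per_metric[m][f"{ts}|{arch}"] = [mean, std]
                minority_f1[f"{ts}|{arch}"] = float(np.mean(min_f1))
                per_class_f1[f"{ts}|{arch}"] = {
                    c: float(np.mean(v)) for c, v in cls_f1.items()
                }
            # two-way ANOVA per metric: training sets x classifiers,
            # replicates = per-class value per trial
            anova = {}
            if len(cfg.archs) < 2:
                anova["skipped"] = "classifier factor needs >= 2 levels"
            for m in per_metric if len(cfg.archs) >= 2 else ():
                table = np.zeros((len(TRAINING_SETS), len(cfg.archs),
                                  len(CLASS_LABELS) * cfg.n_trials))
                for i, ts in enumerate(TRAINING_SETS):
                    for j, arch in enumerate(cfg.archs):
                        sub = df[(df.training_set == ts)
                                 & (df.arch == arch)]
                        vals = []
                        for trial, tsub in sub.groupby("trial"):
                            cm = ce.confusion(tsub["true"],
                                              tsub["predicted"])
                            metrics = ce.per_class_metrics(cm)
                            vals.extend(getattr(metrics, m).values())
                        table[i, j, :] = vals
                res = ce.anova_two_way(table)
                anova[m] = {
                    "f_ratio": res.f_ratio, "critical_f": res.critical_f,
                    "p_value": res.p_value, "df": [res.df_factor,
                                                   res.df_error],
                }
            result = {"macro": per_metric, "minority_f1": minority_f1,
                      "per_class_minority_f1": per_class_f1,
                      "anova": anova}
            with open(out_json, "w") as fh:
                json.dump(result, fh, indent=1)
            # macro table (mean±std per training set x classifier x metric)
            macro_rows = []
            for m, cells in per_metric.items():
                for key, (mean, std) in cells.items():
                    ts, arch = key.split("|")
                    macro_rows.append({
                        "training_set": ts, "classifier": arch,
                        "metric": m, "mean": round(mean, 4),
                        "std": round(std, 4),
                    })
            pd.DataFrame(macro_rows).to_csv(self.out / "macro_report.csv",
                                            index=False)
            if anova and "skipped" not in anova:
                pd.DataFrame([
                    {"metric": m, **v} for m, v in anova.items()
                ]).to_csv(self.out / "anova.csv", index=False)
            # confusion matrices for the first trial of every pair
            from . import plots
            figures = self.out / "figures"
            figures.mkdir(exist_ok=True)
            for (ts, arch), sub in df.groupby(["training_set", "arch"]):
                tsub = sub[sub.trial == 0]
                cm = ce.confusion(tsub["true"], tsub["predicted"])
                plots.confusion_heatmap(
                    cm, CLASS_LABELS,
                    figures / f"confusion_{arch}_{ts}.png",
                    title=f"{arch}, {ts} training set",
                )

        self.runner.run("eval-clf", dep, [out_json], _run)
        with open(out_json) as fh:
            return json.load(fh)

    # ----------------------------------------------------------------------
    def run(self) -> dict:
        corpus_dir = self.simulate()
        split = self.preprocess(corpus_dir)
        feats = self.features(corpus_dir, split)
        trained = self.train_vaes(feats)
        syn_npz = self.generate(trained, feats)
        gen_eval = self.eval_generative(feats, syn_npz)
        pred_csv = self.train_classifiers(feats, syn_npz)
        clf_eval = self.eval_classifiers(pred_csv)
        self.report = {"generative": gen_eval, "classification": clf_eval}
        with open(self.out / "report.json", "w") as fh:
            json.dump(self.report, fh, indent=1)
        return self.report


def run_experiment(config: ExperimentConfig) -> dict:
    return Experiment(config).run()
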