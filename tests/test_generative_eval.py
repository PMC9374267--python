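"""Generative-quality metrics: FAD closed forms and aggregation,
cross-correlation protocol, DTW-MCD with brute-force oracles."""

import numpy as np
import pytest

from respaug import generative_eval as ge
from respaug.generative_eval import (
    MCD_CONST,
    CCSummary,
    EmbeddingStats,
    cc_matrix,
    embed_audio,
    fad_per_class,
    frechet_distance,
    mcd,
    mcd_summary,
    mean_fad,
    ncc,
)
from respaug.preprocess import SEGMENT_SAMPLES

from conftest import make_segment

SR = 22050


def tone(f0, n=SR * 2, amp=0.3):
    t = np.arange(n) / SR
    return amp * np.sin(2 * np.pi * f0 * t)


class TestEmbedder:
    def test_identical_waveforms_identical_embeddings(self):
        w = tone(300.0)
        assert np.array_equal(embed_audio(w), embed_audio(w))

    def test_default_output_length_twice_n_mels(self):
        assert len(embed_audio(tone(300.0))) == 2 * 64

    def test_tones_differ_most_in_their_own_bands(self):
        from respaug.features import mel_center_freqs
        d = np.abs(embed_audio(tone(440.0)) - embed_audio(tone(3000.0)))
        band_means = d[:64]
        centers = mel_center_freqs(64, SR)
        top = np.argsort(band_means)[-6:]
        lo = np.abs(centers - 440.0).argmin()
        hi = np.abs(centers - 3000.0).argmin()
        assert any(abs(int(b) - lo) <= 1 for b in top)
        assert any(abs(int(b) - hi) <= 1 for b in top)

    def test_unknown_embedder_lists_registered(self):
        with pytest.raises(ValueError, match="logmel-stats"):
            embed_audio(tone(300.0), embedder="vggish-missing")


class TestFrechetDistance:
    def test_identical_stats_give_zero(self):
        s = EmbeddingStats(np.array([1.0, 2.0]), np.eye(2), 10)
        assert frechet_distance(s, s) == pytest.approx(0.0, abs=1e-12)

    def test_1d_mean_shift_closed_form(self):
        a = EmbeddingStats(np.array([0.0]), np.array([[1.0]]), 10)
        b = EmbeddingStats(np.array([2.0]), np.array([[1.0]]), 10)
        assert frechet_distance(a, b) == pytest.approx(4.0)

    def test_1d_variance_change_closed_form(self):
        a = EmbeddingStats(np.array([0.0]), np.array([[1.0]]), 10)
        b = EmbeddingStats(np.array([0.0]), np.array([[4.0]]), 10)
        # (sigma1 - sigma2)^2 = 1 + 4 - 2*2 = 1
        assert frechet_distance(a, b) == pytest.approx(1.0)

    def test_symmetric_on_diagonal_gaussians(self):
        rng = np.random.default_rng(0)
        a = EmbeddingStats(rng.normal(size=3), np.diag(rng.random(3) + 0.1),
                           10)
        b = EmbeddingStats(rng.normal(size=3), np.diag(rng.random(3) + 0.1),
                           10)
        assert frechet_distance(a, b) == pytest.approx(
            frechet_distance(b, a), rel=1e-10
        )
        # diagonal closed form: sum (mu_i-nu_i)^2 + (s_i - t_i)^2
        closed = (((a.mu - b.mu) ** 2).sum()
                  + ((np.sqrt(np.diag(a.sigma))
                      - np.sqrt(np.diag(b.sigma))) ** 2).sum())
        assert frechet_distance(a, b) == pytest.approx(closed, rel=1e-8)

    def test_dimension_mismatch_rejected(self):
        a = EmbeddingStats(np.zeros(2), np.eye(2), 5)
        b = EmbeddingStats(np.zeros(3), np.eye(3), 5)
        with pytest.raises(ValueError):
            frechet_distance(a, b)


class TestFadAggregation:
    def test_printed_per_class_values_average_to_model_means(self):
        """Averaging six per-class FAD scores reproduces each generative
        model's headline average to 2 decimals."""
        tables = {
            12.42: {"Bronchiectasis": 28.40, "Bronchiolitis": 11.72,
                    "Healthy": 4.81, "Pneumonia": 12.34, "LRTI": 3.16,
                    "URTI": 14.11},
            11.58: {"Bronchiectasis": 12.47, "Bronchiolitis": 10.86,
                    "Healthy": 12.05, "Pneumonia": 11.56, "LRTI": 12.10,
                    "URTI": 10.44},
            11.64: {"Bronchiectasis": 13.96, "Bronchiolitis": 10.88,
                    "Healthy": 12.07, "Pneumonia": 11.62, "LRTI": 10.79,
                    "URTI": 10.57},
        }
        for expected, per_class in tables.items():
            # one headline average is truncated rather than rounded
            # (11.6483 printed as 11.64), so compare at the 0.01 level
            assert mean_fad(per_class) == pytest.approx(expected, abs=0.01)

    def test_bootstrap_resample_has_near_zero_fad(self):
        rng = np.random.default_rng(0)
        real = [make_segment(rng.normal(size=SEGMENT_SAMPLES) * 0.2,
                             label="URTI") for _ in range(12)]
        resampled = [real[i] for i in rng.integers(0, 12, size=12)]
        fads, mean = fad_per_class(real, resampled)
        noise = [make_segment(rng.uniform(-1, 1, SEGMENT_SAMPLES),
                              label="URTI") for _ in range(12)]
        _, mean_noise = fad_per_class(real, noise)
        assert mean < 0.1 * mean_noise

    def test_missing_class_rejected(self):
        rng = np.random.default_rng(0)
        real = [make_segment(rng.normal(size=SEGMENT_SAMPLES), label="URTI")
                for _ in range(3)]
        syn = [make_segment(rng.normal(size=SEGMENT_SAMPLES), label="LRTI")
               for _ in range(3)]
        with pytest.raises(ValueError, match="missing"):
            fad_per_class(real, syn)


class TestNcc:
    def test_identical_signals_give_one(self):
        x = tone(200.0)
        assert ncc(x, x) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self):
        x = tone(200.0)
        assert ncc(x, -x) == pytest.approx(-1.0)

    def test_quadrature_tones_orthogonal(self):
        n = SR  # integer number of 100 Hz periods
        t = np.arange(n) / SR
        s = np.sin(2 * np.pi * 100 * t)
        c = np.cos(2 * np.pi * 100 * t)
        assert abs(ncc(s, c)) < 1e-10

    def test_zero_energy_defined_as_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert ncc(np.zeros(100), np.ones(100) * 2) == 0.0


class TestCcMatrix:
    def test_copies_give_unit_diagonal(self):
        rng = np.random.default_rng(0)
        real = {c: [rng.normal(size=500) for _ in range(4)]
                for c in ("URTI", "LRTI")}
        summary = cc_matrix(real, {c: list(v) for c, v in real.items()},
                            n_per_class=4, rng=np.random.default_rng(1))
        for c in real:
            assert summary.mean[c][c] == pytest.approx(1.0)

    def test_all_entries_in_unit_interval(self):
        rng = np.random.default_rng(2)
        real = {c: [rng.normal(size=300) for _ in range(5)]
                for c in ("URTI", "LRTI")}
        syn = {c: [rng.normal(size=300) for _ in range(5)]
               for c in ("URTI", "LRTI")}
        s = cc_matrix(real, syn, n_per_class=5,
                      rng=np.random.default_rng(3))
        for row in s.mean.values():
            assert all(-1 <= v <= 1 for v in row.values())

    def test_matches_exhaustive_double_loop(self):
        rng = np.random.default_rng(4)
        real = {"URTI": [rng.normal(size=200) for _ in range(3)]}
        syn = {"URTI": [rng.normal(size=200) for _ in range(3)]}
        s = cc_matrix(real, syn, n_per_class=3,
                      rng=np.random.default_rng(0))
        maxima = [max(ncc(sw, rw) for rw in real["URTI"])
                  for sw in syn["URTI"]]
        assert s.mean["URTI"]["URTI"] == pytest.approx(np.mean(maxima))
        assert s.std["URTI"]["URTI"] == pytest.approx(np.std(maxima))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cc_matrix({"URTI": []}, {"URTI": [np.ones(10)]}, 2)


class TestMcd:
    def test_identical_matrices_give_zero(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(13, 20))
        assert mcd(m, m) == pytest.approx(0.0, abs=1e-12)

    def test_unit_offset_closed_form(self):
        """A +1 offset in one coefficient at every frame gives
        10*sqrt(2)/ln(10) ~ 6.1419 when DTW reduces to the identity path."""
        rng = np.random.default_rng(1)
        # strongly distinct frames so any path detour costs more
        m = np.cumsum(rng.normal(size=(13, 15)) + 2.0, axis=1)
        shifted = m.copy()
        shifted[5] += 1.0
        assert mcd(m, shifted) == pytest.approx(MCD_CONST, rel=1e-9)
        assert MCD_CONST == pytest.approx(6.1419, abs=1e-4)

    def test_c0_excluded_by_default(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(13, 10))
        shifted = m.copy()
        shifted[0] += 100.0  # energy row only
        assert mcd(m, shifted) == pytest.approx(0.0, abs=1e-12)
        assert mcd(m, shifted, include_c0=True) > 1.0

    def test_dtw_alignment_not_worse_than_identity(self):
        rng = np.random.default_rng(3)
        m = np.cumsum(rng.normal(size=(13, 30)), axis=1)
        rolled = np.concatenate([m[:, :5], m[:, :-5]], axis=1)
        aligned = mcd(m, rolled)
        identity = MCD_CONST * np.mean(
            np.sqrt(((m[1:] - rolled[1:]) ** 2).sum(axis=0))
        )
        assert aligned <= identity + 1e-12


class TestMcdSummary:
    def test_copies_give_zero_mean(self):
        rng = np.random.default_rng(0)
        segs = [make_segment(rng.normal(size=SEGMENT_SAMPLES) * 0.1,
                             label="URTI") for _ in range(3)]
        s = mcd_summary({"URTI": segs}, {"URTI": list(segs)}, n_per_class=3,
                        rng=np.random.default_rng(1))
        # every (synthetic, real) pair includes identical pairs; the mean
        # over all pairs is strictly positive unless sets are singletons
        single = mcd_summary({"URTI": segs[:1]}, {"URTI": segs[:1]},
                             n_per_class=1, rng=np.random.default_rng(1))
        assert single.mean["URTI"] == pytest.approx(0.0, abs=1e-12)
        assert s.mean["URTI"] >= 0.0

    def test_matches_hand_double_loop(self):
        from respaug.features import mfcc
        rng = np.random.default_rng(5)
        real = [make_segment(rng.normal(size=SEGMENT_SAMPLES) * 0.1,
                             label="URTI") for _ in range(2)]
        syn = [make_segment(rng.normal(size=SEGMENT_SAMPLES) * 0.1,
                            label="URTI") for _ in range(2)]
        s = mcd_summary({"URTI": real}, {"URTI": syn}, n_per_class=2,
                        rng=np.random.default_rng(0))
        values = [mcd(mfcc(r), mfcc(sw)) for sw in syn for r in real]
        assert s.mean["URTI"] == pytest.approx(np.mean(values))
        assert s.std["URTI"] == pytest.approx(np.std(values))
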