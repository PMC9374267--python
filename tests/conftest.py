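"""Shared fixtures: a tiny synthetic corpus for unit tests and one
session-scoped desk-preset experiment reused by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from respaug import io as ricio
from respaug import preprocess as pp
from respaug import synth
from respaug.pipeline import ExperimentConfig, Experiment


@pytest.fixture(scope="session")
def tiny_corpus_dir(tmp_path_factory):
    """A small 7-class corpus: 6 cycles per class, fixed seed."""
    out = tmp_path_factory.mktemp("tiny_corpus")
    cfg = synth.SynthConfig(
        cycles_per_class={c: 6 for c in ricio.CLASS_LABELS}, seed=42
    )
    synth.generate_corpus(cfg, out)
    return out


@pytest.fixture(scope="session")
def tiny_recordings(tiny_corpus_dir):
    return ricio.load_corpus(tiny_corpus_dir)


@pytest.fixture(scope="session")
def tiny_segments(tiny_recordings):
    return pp.segment_corpus(tiny_recordings)


@pytest.fixture(scope="session")
def desk_experiment(tmp_path_factory):
    """Full desk-preset experiment (ICBHI-like imbalance, seed 1).

    The heaviest fixture in the suite; the generative and classification
    acceptance checks all read from its report.
    """
    out = tmp_path_factory.mktemp("desk_experiment")
    config = ExperimentConfig(out_dir=str(out), preset="desk", seed=1)
    exp = Experiment(config)
    report = exp.run()
    return {"config": config, "out": out, "report": report}


def make_segment(waveform: np.ndarray, label: str = "URTI",
                 source=("101_1b1_Al_sc_Synth", 0),
                 duration_s: float = 6.0) -> pp.AudioSegment:
    """Build a 6 s AudioSegment from an arbitrary-length waveform."""
    buf = np.zeros(pp.SEGMENT_SAMPLES)
    n = min(len(waveform), pp.SEGMENT_SAMPLES)
    buf[:n] = waveform[:n]
    return pp.AudioSegment(buf, label, source, duration_s)
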