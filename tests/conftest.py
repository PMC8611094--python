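"""Shared fixtures: small deterministic workspaces and synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from rg4scape.synthetic_data import (
    SimulationConfig,
    generate_transcriptome,
)
from rg4scape.transcriptome import Interval, TranscriptAnnotation


@pytest.fixture(scope="session")
def toy_annotation():
    """Three transcripts with distinct feature layouts."""
    return {
        "T1": TranscriptAnnotation("T1", 50, 300, 100),
        "T2": TranscriptAnnotation("T2", 100, 600, 200),
        "T3": TranscriptAnnotation("T3", 0, 400, 0),
    }


@pytest.fixture(scope="session")
def default_sim():
    """One default-config synthetic dataset shared across tests."""
    cfg = SimulationConfig(seed=20)
    sequences, annotations, truth = generate_transcriptome(cfg)
    return cfg, sequences, annotations, truth


def random_intervals(rng, annotations, n, max_len=60):
    """Valid random intervals over a workspace (test helper)."""
    tids = sorted(annotations)
    out = []
    for _ in range(n):
        tid = tids[rng.integers(len(tids))]
        L = annotations[tid].length
        length = int(rng.integers(1, min(max_len, L) + 1))
        s = int(rng.integers(0, L - length + 1))
        out.append(Interval(tid, s, s + length))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
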