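"""Shared fixtures and independent oracles.

The brute-force scorer here deliberately shares no code with
``mucistarget.pwm``: pure-Python double loops, its own complement table and
log-odds arithmetic. It is the reference against which the vectorized
implementation is checked.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from mucistarget.pipeline import RunConfig, run_sample
from mucistarget.synthetic import FixtureSpec, generate_fixture

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def brute_force_score(matrix, bg, seq, floor=0.001):
    """Independent O(L*W) double-loop normalized scorer over both strands."""
    L = len(matrix)
    lo = [
        [math.log(max(matrix[i][b], floor) / bg[b]) for b in range(4)]
        for i in range(L)
    ]
    n_val = math.log(floor / max(bg))

    def best_raw(s):
        best = -math.inf
        for off in range(len(s) - L + 1):
            total = 0.0
            for i in range(L):
                c = s[off + i]
                total += n_val if c == "N" else lo[i]["ACGT".index(c)]
            best = max(best, total)
        return best

    rc = "".join(_COMP[c] for c in reversed(seq.upper()))
    best = max(best_raw(seq.upper()), best_raw(rc))
    min_raw = sum(min(row) for row in lo)
    max_raw = sum(max(row) for row in lo)
    if max_raw == min_raw:
        return 0.0
    return min(1.0, max(0.0, (best - min_raw) / (max_raw - min_raw)))


def random_pwm_matrix(rng, length, peaked=False):
    """A random L x 4 probability matrix; ``peaked`` concentrates each column."""
    if peaked:
        mat = np.full((length, 4), 0.03)
        mat[np.arange(length), rng.integers(0, 4, size=length)] = 0.91
    else:
        mat = rng.random((length, 4)) + 0.05
        mat /= mat.sum(axis=1, keepdims=True)
    return mat


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """One default synthetic dataset shared across the session."""
    out = tmp_path_factory.mktemp("fixture") / "fx"
    truth = generate_fixture(FixtureSpec(seed=7), out)
    return out, truth


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir, tmp_path_factory):
    out_dir = tmp_path_factory.mktemp("run")
    path, truth = fixture_dir
    config = RunConfig.from_yaml(path / "config.yaml")
    result = run_sample(config, out_dir=out_dir)
    return result, truth, out_dir
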