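"""Position weight matrices and MotifLocator-style normalized log-odds scoring.

A PWM is a position-probability matrix over (A, C, G, T). Sequences are
scored on both strands with a sliding window; the best raw log-odds sum is
normalized per matrix to [0, 1] as ``(raw - min_raw) / (max_raw - min_raw)``,
where ``min_raw``/``max_raw`` are the column-wise minimum/maximum achievable
sums. On this scale 1.0 means a window attains the matrix optimum (the
consensus) and 0.0 the anti-consensus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: default probability floor applied before taking log-odds (avoids -inf)
DEFAULT_FLOOR_PROB = 0.001
#: default pseudocount for count matrices
DEFAULT_PSEUDOCOUNT = 1.0


class DegenerateMatrixError(ValueError):
    """Raised when a count matrix cannot be normalized (all-zero row, no pseudocount)."""


@dataclass(frozen=True)
class BackgroundModel:
    """Zero-order background nucleotide model.

    frequencies : length-4 array of probabilities over (A, C, G, T), all > 0.
    """

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", freqs)
        if freqs.shape != (4,):
            raise ValueError("background model needs exactly 4 frequencies (A,C,G,T)")
        if not np.all(freqs > 0):
            raise ValueError("background frequencies must all be > 0")
        if abs(float(freqs.sum()) - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_sequences(cls, sequences, pseudocount: float = 1.0) -> "BackgroundModel":
        """Estimate frequencies by counting A/C/G/T over an iterable of sequences."""
        counts = np.zeros(4)
        for seq in sequences:
            seq = seq.upper()
            for i, base in enumerate(ALPHABET):
                counts[i] += seq.count(base)
        counts += pseudocount
        return cls(counts / counts.sum())


@dataclass(frozen=True)
class PWM:
    """A position-probability matrix annotated to zero or more TF gene symbols."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    tf_annotations: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "tf_annotations", frozenset(self.tf_annotations))
        if not self.motif_id:
            raise ValueError("motif_id must be non-empty")
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if mat.shape[0] < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        if np.any(mat < -1e-12):
            raise ValueError(f"{self.motif_id}: probabilities must be >= 0")
        if np.any(np.abs(mat.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError(f"{self.motif_id}: each position must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        """Highest-probability base at each position."""
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def anti_consensus(self) -> str:
        """Lowest-probability base at each position."""
        return "".join(ALPHABET[i] for i in self.matrix.argmin(axis=1))


def pwm_from_counts(
    counts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    motif_id: str = "pwm",
    tf_annotations=(),
) -> PWM:
    """Normalize an L x 4 count (or probability) matrix into a PWM.

    Each row becomes ``(count + pseudocount) / (row_sum + 4 * pseudocount)``.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] != 4:
        raise ValueError("counts must be an L x 4 matrix")
    if counts.shape[0] < 4:
        raise ValueError("motif length must be >= 4")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    row_sums = counts.sum(axis=1)
    if pseudocount == 0 and np.any(row_sums == 0):
        raise DegenerateMatrixError("all-zero row with pseudocount 0")
    probs = (counts + pseudocount) / (row_sums + 4 * pseudocount)[:, None]
    return PWM(motif_id=motif_id, matrix=probs, tf_annotations=frozenset(tf_annotations))


def logodds_matrix(
    pwm: PWM, bg: BackgroundModel, floor_prob: float = DEFAULT_FLOOR_PROB
) -> np.ndarray:
    """L x 4 matrix of ``ln(max(p, floor_prob) / bg)``, finite everywhere."""
    if not (0 < floor_prob < 0.25):
        raise ValueError("floor_prob must be in (0, 0.25)")
    return np.log(np.maximum(pwm.matrix, floor_prob) / bg.frequencies[None, :])


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; case-insensitive, returns uppercase."""
    seq = seq.upper()
    _validate_alphabet(seq)
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_alphabet(seq: str) -> None:
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")


def encode_sequence(seq: str) -> np.ndarray:
    """Integer-encode an uppercase DNA string (A=0 C=1 G=2 T=3 N=4)."""
    return np.fromiter((_BASE_INDEX[b] for b in seq), dtype=np.int64, count=len(seq))


def score_window(
    pwm: PWM,
    bg: BackgroundModel,
    seq: str,
    floor_prob: float = DEFAULT_FLOOR_PROB,
) -> float:
    """Best normalized log-odds score of ``pwm`` over all offsets of ``seq``, both strands.

    N positions contribute the worst-case log-odds ``ln(floor_prob / max(bg))``
    so N-rich windows cannot score spuriously high. The result is in [0, 1];
    a degenerate matrix (max_raw == min_raw) scores 0 with a logged warning.
    """
    seq = seq.upper()
    _validate_alphabet(seq)
    L = pwm.length
    if len(seq) < L:
        raise ValueError(
            f"sequence length {len(seq)} shorter than motif {pwm.motif_id} length {L}"
        )

    lo = logodds_matrix(pwm, bg, floor_prob)
    n_value = math.log(floor_prob / float(bg.frequencies.max()))
    # column 4 = N: worst case at every position
    lo5 = np.concatenate([lo, np.full((L, 1), n_value)], axis=1)

    min_raw = float(lo.min(axis=1).sum())
    max_raw = float(lo.max(axis=1).sum())
    denom = max_raw - min_raw
    if denom <= 0:
        log.warning("degenerate constant matrix %s; score defined as 0", pwm.motif_id)
        return 0.0

    best = -math.inf
    for strand_seq in (seq, reverse_complement(seq)):
        codes = encode_sequence(strand_seq)
        # all L-mer windows as a (n_offsets, L) view
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        raws = lo5[np.arange(L)[None, :], windows].sum(axis=1)
        best = max(best, float(raws.max()))

    score = (best - min_raw) / denom
    return min(1.0, max(0.0, score))
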