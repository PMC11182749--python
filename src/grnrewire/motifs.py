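"""Position-weight-matrix handling and log-odds motif scanning.

PWMs are read from and written to the JASPAR count format via Biopython.
Scanning scores every window on both strands with the log2 odds
sum(log2(p_base / q_base)) against a uniform background and calls a hit when
the score reaches a stated fraction of the motif's maximum attainable score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

_ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


@dataclass
class PWM:
    """A probability PWM with uniform-background log-odds scoring."""

    motif_id: str
    tf_names: tuple[str, ...]
    probabilities: np.ndarray  # (length, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4:
            raise ValueError("PWM probabilities must be (length, 4)")
        if p.shape[0] < 4:
            raise ValueError("PWM length must be >= 4")
        if np.any(p <= 0):
            raise ValueError("PWM probabilities must be positive (apply a pseudocount)")
        self.probabilities = p / p.sum(axis=1, keepdims=True)

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        tf_names: tuple[str, ...],
        counts: np.ndarray,
        pseudocount: float = 0.01,
    ) -> "PWM":
        c = np.asarray(counts, dtype=float) + pseudocount
        return cls(motif_id, tuple(tf_names), c / c.sum(axis=1, keepdims=True))

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probabilities / self.background)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.probabilities.argmax(axis=1))


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes (A,C,G,T -> 0..3; anything else 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def reverse_complement(seq: str) -> str:
    table = str.maketrans("ACGTN", "TGCAN")
    return seq.upper().translate(table)[::-1]


def _window_scores(codes: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Log-odds score of every window; windows containing N score -inf."""
    length = log_odds.shape[0]
    n_win = len(codes) - length + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)
    valid = ~(windows == 4).any(axis=1)
    # score[w] = sum_pos log_odds[pos, windows[w, pos]]; N windows masked after
    safe = np.where(windows == 4, 0, windows)
    scores = log_odds[np.arange(length)[None, :], safe].sum(axis=1)
    scores[~valid] = -np.inf
    return scores


def scan_motifs(
    sequences: dict[str, str],
    pwms: list[PWM],
    score_fraction: float = 0.8,
) -> pd.DataFrame:
    """Scan sequences for motif hits on both strands.

    A hit is any window whose log-odds score is at least ``score_fraction``
    of the motif's maximum score.  Positions are 0-based starts on the
    forward strand regardless of the hit strand.

    Returns
    -------
    DataFrame with ``sequence``, ``motif_id``, ``position``, ``strand``,
    ``score`` (sorted deterministically).
    """
    if not 0 < score_fraction <= 1:
        raise ValueError("score_fraction must be in (0, 1]")
    rows = []
    for seq_name in sequences:
        seq = sequences[seq_name]
        fwd = encode_sequence(seq)
        rev = _COMPLEMENT[fwd][::-1]
        n = len(fwd)
        for pwm in pwms:
            lo = pwm.log_odds
            threshold = score_fraction * pwm.max_score
            for strand, codes in (("+", fwd), ("-", rev)):
                scores = _window_scores(codes, lo)
                for pos in np.flatnonzero(scores >= threshold):
                    fpos = pos if strand == "+" else n - pos - pwm.length
                    rows.append(
                        (seq_name, pwm.motif_id, int(fpos), strand, float(scores[pos]))
                    )
    df = pd.DataFrame(
        rows, columns=["sequence", "motif_id", "position", "strand", "score"]
    )
    return df.sort_values(
        ["sequence", "motif_id", "position", "strand"], kind="mergesort"
    ).reset_index(drop=True)


def write_jaspar(pwms: list[PWM], path, counts_scale: int = 100) -> None:
    """Write PWMs as JASPAR count matrices (probabilities x counts_scale)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            name = pwm.tf_names[0] if pwm.tf_names else pwm.motif_id
            fh.write(f">{pwm.motif_id}\t{name}\n")
            counts = np.round(pwm.probabilities * counts_scale).astype(int)
            for i, base in enumerate(_ALPHABET):
                vals = " ".join(str(v) for v in counts[:, i])
                fh.write(f"{base}  [ {vals} ]\n")


def read_jaspar(path, pseudocount: float = 0.01) -> list[PWM]:
    """Read a JASPAR-format PWM file (via Bio.motifs) into PWM objects."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in _ALPHABET] for i in range(m.length)])
        name = m.name or m.matrix_id
        pwms.append(
            PWM.from_counts(m.matrix_id, (name,), counts, pseudocount=pseudocount)
        )
    return pwms
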