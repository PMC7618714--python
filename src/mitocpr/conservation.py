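"""Per-column and sliding-window conservation of protein alignments.

Used to localize function within a protein from an ortholog alignment:
per-column scores in [0, 1], a sliding-window mean profile (default
five-residue window), and a prefix-vs-suffix contrast around a chosen
boundary (e.g. the first 25 residues of a targeting sequence).

The primary column score is sum-of-pairs identity: the fraction of
unordered non-gap residue pairs in a column that are identical.  A
BLOSUM62-based variant rescales mean pairwise substitution scores to
[0, 1] for similarity-aware profiles.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from mitocpr.io import SequenceRecord

DEFAULT_WINDOW = 5
DEFAULT_BOUNDARY = 25

_BLOSUM = substitution_matrices.load("BLOSUM62")
_BLOSUM_MIN = min(
    _BLOSUM[a, b] for a, b in combinations("ACDEFGHIKLMNPQRSTVWY", 2)
)


@dataclasses.dataclass(frozen=True)
class ConservationProfile:
    """Column scores plus the windowed profile derived from them."""

    column_scores: np.ndarray
    window: int
    window_scores: np.ndarray
    window_start_positions: np.ndarray  # 1-based window starts

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        cols = pd.DataFrame(
            {
                "column": np.arange(1, self.column_scores.size + 1),
                "column_score": self.column_scores,
            }
        )
        wins = pd.DataFrame(
            {
                "window_start": self.window_start_positions,
                "window_score": self.window_scores,
            }
        )
        return cols, wins


def _pair_score(residues: list[str], score: str) -> float:
    if len(residues) < 2:
        return 0.0
    if score == "identity_pairs":
        same = sum(a == b for a, b in combinations(residues, 2))
        n = len(residues)
        return same / (n * (n - 1) / 2)
    if score == "blosum_pairs":
        # each pair rescaled against its own residues' diagonal maximum,
        # so an identical pair always scores 1 and the worst mismatch 0
        vals = [
            (_BLOSUM[a, b] - _BLOSUM_MIN)
            / (max(_BLOSUM[a, a], _BLOSUM[b, b]) - _BLOSUM_MIN)
            for a, b in combinations(residues, 2)
        ]
        return float(np.clip(np.mean(vals), 0.0, 1.0))
    raise ValueError(f"unknown score {score!r}")


def column_conservation(
    alignment: list[SequenceRecord], score: str = "identity_pairs"
) -> np.ndarray:
    """Score every alignment column in [0, 1].

    Pairs involving a gap are excluded from numerator and denominator;
    columns with fewer than two non-gap residues score 0.
    """
    if len(alignment) < 2:
        raise ValueError("conservation needs at least two sequences")
    lengths = {len(r) for r in alignment}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    n_cols = lengths.pop()

    out = np.empty(n_cols)
    for c in range(n_cols):
        residues = [r.sequence[c] for r in alignment if r.sequence[c] not in "-X"]
        out[c] = _pair_score(residues, score)
    return out


def sliding_window(column_scores: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Arithmetic mean over each contiguous window of columns."""
    scores = np.asarray(column_scores, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > scores.size:
        raise ValueError(f"window {window} exceeds {scores.size} columns")
    kernel = np.ones(window) / window
    return np.convolve(scores, kernel, mode="valid")


def conservation_profile(
    alignment: list[SequenceRecord],
    window: int = DEFAULT_WINDOW,
    score: str = "identity_pairs",
) -> ConservationProfile:
    cols = column_conservation(alignment, score=score)
    wins = sliding_window(cols, window=window)
    starts = np.arange(1, cols.size - window + 2)
    return ConservationProfile(
        column_scores=cols,
        window=window,
        window_scores=wins,
        window_start_positions=starts,
    )


def prefix_contrast(
    profile: ConservationProfile, boundary: int = DEFAULT_BOUNDARY
) -> tuple[float, float, float]:
    """Mean windowed conservation before vs after a residue boundary.

    The prefix mean covers windows lying entirely within columns
    1..boundary; the suffix mean covers windows starting after the
    boundary.  Windows straddling the boundary belong to neither side.

    Returns (mean_prefix, mean_suffix, difference).
    """
    starts = profile.window_start_positions
    ends = starts + profile.window - 1
    prefix = profile.window_scores[ends <= boundary]
    suffix = profile.window_scores[starts > boundary]
    if prefix.size == 0:
        raise ValueError(f"no complete window within columns 1..{boundary}")
    if suffix.size == 0:
        raise ValueError(f"no window starts after column {boundary}")
    mean_prefix = float(prefix.mean())
    mean_suffix = float(suffix.mean())
    return mean_prefix, mean_suffix, mean_prefix - mean_suffix
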