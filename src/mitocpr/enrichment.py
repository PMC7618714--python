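"""Positional amino-acid enrichment of mitochondrial targeting sequences.

N-terminal targeting presequences have a characteristic composition
(arginine-rich, hydrophobic, devoid of acidic residues).  This module
quantifies that composition position by position over the first
``n_positions`` residues of a presequence set, as the log2 ratio of the
observed positional frequency to the proteome-wide usage of each
residue, and identifies residues of a query presequence absent from a
reference set at the same position.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from mitocpr.io import SequenceRecord
from mitocpr.simulate import AMINO_ACIDS

logger = logging.getLogger(__name__)

_SKIP = set("X*-")  # non-standard symbols ignored in counting

DEFAULT_N_POSITIONS = 20


@dataclasses.dataclass(frozen=True)
class BackgroundFrequencies:
    """Proteome-wide amino-acid usage."""

    freqs: dict[str, float]
    source_n_residues: int

    def __post_init__(self) -> None:
        if set(self.freqs) != set(AMINO_ACIDS):
            raise ValueError("background must cover the 20 standard residues")
        total = sum(self.freqs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"background frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.freqs.values()):
            raise ValueError("negative background frequency")

    def as_array(self) -> np.ndarray:
        return np.array([self.freqs[a] for a in AMINO_ACIDS])


def background_frequencies(proteome: list[SequenceRecord]) -> BackgroundFrequencies:
    """Amino-acid usage over all positions of all proteome sequences.

    Non-standard symbols ('X', '*', '-') are skipped and counted; raises
    if no standard residue is left.
    """
    if not proteome:
        raise ValueError("empty proteome")
    counts = dict.fromkeys(AMINO_ACIDS, 0)
    skipped = 0
    for rec in proteome:
        for ch in rec.sequence:
            if ch in counts:
                counts[ch] += 1
            elif ch in _SKIP:
                skipped += 1
            else:
                raise ValueError(f"unexpected symbol {ch!r} in {rec.id}")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable standard residues in proteome")
    if skipped:
        logger.info("skipped %d non-standard symbols", skipped)
    return BackgroundFrequencies(
        freqs={a: c / total for a, c in counts.items()}, source_n_residues=total
    )


def positional_enrichment(
    presequences: list[SequenceRecord],
    background: BackgroundFrequencies,
    n_positions: int = DEFAULT_N_POSITIONS,
    pseudocount: float | None = None,
    floor: float | None = None,
) -> pd.DataFrame:
    """Log2 positional enrichment over the first ``n_positions`` residues.

    For position p and residue a,
    ``E(p, a) = log2((f_obs(p, a) + eps) / (f_bg(a) + eps))`` where
    ``f_obs`` is the fraction of set sequences carrying a at p and the
    pseudocount ``eps`` defaults to 1/(2·n_sequences), so an unobserved
    residue yields a finite negative value.  Sequences shorter than
    ``n_positions`` are dropped (logged), not padded.  ``floor`` clamps
    the output at ±floor for display.

    Returns a DataFrame with positions 1..n_positions as the index and
    the 20 amino acids as columns; ``attrs`` carries ``n_sequences`` and
    ``pseudocount``.
    """
    usable = [r for r in presequences if len(r.sequence) >= n_positions]
    n_dropped = len(presequences) - len(usable)
    if n_dropped:
        logger.info("dropped %d sequence(s) shorter than %d", n_dropped, n_positions)
    if not usable:
        raise ValueError("no sequence reaches n_positions after length filtering")

    n = len(usable)
    eps = 1.0 / (2.0 * n) if pseudocount is None else float(pseudocount)
    f_bg = background.as_array()

    counts = np.zeros((n_positions, 20))
    aa_index = {a: j for j, a in enumerate(AMINO_ACIDS)}
    observed = np.zeros(n_positions)
    for rec in usable:
        for p in range(n_positions):
            j = aa_index.get(rec.sequence[p])
            if j is not None:  # 'X' etc. excluded from the position count
                counts[p, j] += 1
                observed[p] += 1
    f_obs = counts / observed[:, None]

    with np.errstate(divide="ignore"):
        e = np.log2((f_obs + eps) / (f_bg[None, :] + eps))
    if floor is not None:
        e = np.clip(e, -abs(floor), abs(floor))

    out = pd.DataFrame(e, index=pd.RangeIndex(1, n_positions + 1, name="position"),
                       columns=list(AMINO_ACIDS))
    out.attrs["n_sequences"] = n
    out.attrs["pseudocount"] = eps
    return out


def unique_features(
    query: SequenceRecord,
    reference_set: list[SequenceRecord],
    n_positions: int = DEFAULT_N_POSITIONS,
) -> list[tuple[int, str]]:
    """Query residues absent from every reference at the same position.

    Returns ``(position, residue)`` pairs, 1-based, ordered by position.
    A reference shorter than a position simply does not constrain it.
    An empty reference set returns every position (with a warning).
    """
    import warnings

    if len(query.sequence) < n_positions:
        raise ValueError(
            f"query {query.id!r} shorter than n_positions={n_positions}"
        )
    if not reference_set:
        warnings.warn("empty reference set: every query position is 'unique'",
                      stacklevel=2)
        return [(p + 1, query.sequence[p]) for p in range(n_positions)]

    out = []
    for p in range(n_positions):
        a = query.sequence[p]
        if not any(
            len(ref.sequence) > p and ref.sequence[p] == a for ref in reference_set
        ):
            out.append((p + 1, a))
    return out
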