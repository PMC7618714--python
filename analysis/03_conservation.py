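#!/usr/bin/env python
"""Sliding-window conservation of a simulated ortholog alignment.

Simulates a 10-sequence, 80-column gapless protein alignment whose
first 25 columns are strongly conserved (substitution probability 0.05
vs 0.5 elsewhere), mimicking an N-terminal functional element inside an
otherwise divergent targeting sequence, then computes the per-column
identity profile, its 5-residue windowed means, and the
prefix-vs-suffix conservation contrast at residue 25.

Writes results/conservation_profile.tsv and the alignment FASTA.
"""

from pathlib import Path

import pandas as pd

from mitocpr import conservation, io, simulate

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 41


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    records, _ = simulate.simulate_alignment(
        n_seqs=10, length=80, conserved_prefix=25,
        p_sub_conserved=0.05, p_sub_variable=0.5, seed=SEED,
    )
    io.write_fasta(records, RESULTS / "ortholog_alignment.fasta")

    profile = conservation.conservation_profile(records, window=5)
    cols, wins = profile.to_frames()
    merged = cols.merge(wins, how="left", left_on="column", right_on="window_start")
    io.write_table(merged, RESULTS / "conservation_profile.tsv")

    pre, suf, diff = conservation.prefix_contrast(profile, boundary=25)
    print(f"windowed conservation, columns 1-25: {pre:.3f}")
    print(f"windowed conservation, columns 26-80: {suf:.3f}")
    print(f"contrast (prefix - suffix): {diff:.3f}")


if __name__ == "__main__":
    main()
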