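"""Synthetic-data generators with known ground truth.

Each generator emulates the statistical structure one pipeline stage
assumes — plate-structured colony arrays, presequence sets with planted
positional biases, alignments with a conserved N-terminal block, and
bench-assay time series — and returns its ground truth alongside the
data so recovery tests are self-contained.

Determinism contract: every generator is a pure function of its
parameters and ``seed``.  Child generators never share streams; they are
spawned from a single ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from mitocpr.io import SequenceRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Approximate S. cerevisiae proteome amino-acid usage, used as the
# default background for presequence simulation.  Order follows
# AMINO_ACIDS; values renormalized to sum to 1.
YEAST_AA_FREQS = {
    "A": 0.0550, "C": 0.0131, "D": 0.0585, "E": 0.0656, "F": 0.0441,
    "G": 0.0498, "H": 0.0217, "I": 0.0655, "K": 0.0730, "L": 0.0957,
    "M": 0.0207, "N": 0.0613, "P": 0.0438, "Q": 0.0393, "R": 0.0445,
    "S": 0.0902, "T": 0.0592, "V": 0.0556, "W": 0.0104, "Y": 0.0337,
}
_total = sum(YEAST_AA_FREQS.values())
YEAST_AA_FREQS = {a: f / _total for a, f in YEAST_AA_FREQS.items()}


@dataclasses.dataclass
class ScreenSimConfig:
    """Parameters of the colony-array screen generator.

    Defaults describe a realistic arrayed overexpression screen scanned
    at 300 dpi: ~300-pixel colonies, multiplicative plate effects of
    ~15% (log-scale SD), ~15% replicate noise, and a small fraction of
    dead strains.  Hit effects are planted on the selective medium only,
    in SD units of the within-group log-size distribution (plate effect
    plus colony noise combined).
    """

    n_genes: int = 2000
    genes_per_plate: int = 384
    n_replicates: int = 4
    plate_effect_sd: float = 0.15
    colony_noise_cv: float = 0.15
    baseline_size_px: float = 300.0
    dead_fraction: float = 0.0
    n_hits: int = 0
    hit_effect_sd_units: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_hits > self.n_genes:
            raise ValueError("n_hits cannot exceed n_genes")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        for name in ("plate_effect_sd", "colony_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.baseline_size_px <= 0:
            raise ValueError("baseline_size_px must be > 0")
        if self.n_replicates < 1 or self.n_genes < 1 or self.genes_per_plate < 1:
            raise ValueError("counts must be >= 1")


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def simulate_screen(cfg: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-medium colony array with planted activators.

    Colony sizes are log-normal: log size = log(baseline) + plate effect
    + noise, with an additive selective-medium shift of
    ``hit_effect_sd_units`` × sqrt(plate_effect_sd² + noise_sd²) for the
    ``n_hits`` planted genes.  Dead strains (drawn independently of hit
    status) produce <20-pixel colonies on both media.  Each
    (medium, replicate) pair fills its own set of plates so plate
    effects differ between media and replicates.

    Returns
    -------
    (plates, truth)
        ``plates`` is a long-form colony table; ``truth`` maps gene_id
        to ``is_hit``, ``planted_effect`` (log-scale shift) and
        ``is_dead``.
    """
    cfg.validate()
    rng_truth, rng_plate, rng_noise, rng_dead = _spawn(cfg.seed, 4)

    genes = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    hit_idx = rng_truth.choice(cfg.n_genes, size=cfg.n_hits, replace=False)
    is_hit = np.zeros(cfg.n_genes, dtype=bool)
    is_hit[hit_idx] = True
    noise_sd = np.sqrt(np.log1p(cfg.colony_noise_cv**2))
    group_sd = float(np.hypot(cfg.plate_effect_sd, noise_sd))
    effect = np.where(is_hit, cfg.hit_effect_sd_units * group_sd, 0.0)
    is_dead = rng_dead.random(cfg.n_genes) < cfg.dead_fraction

    n_plates = int(np.ceil(cfg.n_genes / cfg.genes_per_plate))
    plate_of_gene = np.arange(cfg.n_genes) // cfg.genes_per_plate
    pos_on_plate = np.arange(cfg.n_genes) % cfg.genes_per_plate
    n_cols = int(np.ceil(np.sqrt(cfg.genes_per_plate)))

    rows = []
    log_base = np.log(cfg.baseline_size_px)
    for medium in ("selective", "permissive"):
        for rep in range(1, cfg.n_replicates + 1):
            plate_effects = rng_plate.normal(0.0, cfg.plate_effect_sd, n_plates)
            noise = rng_noise.normal(0.0, noise_sd, cfg.n_genes)
            log_size = log_base + plate_effects[plate_of_gene] + noise
            if medium == "selective":
                log_size = log_size + effect
            size = np.exp(log_size)
            # dead strains barely grow anywhere: a few pixels of debris
            dead_px = rng_dead.uniform(1.0, 15.0, int(is_dead.sum()))
            size[is_dead] = dead_px
            rows.append(
                pd.DataFrame(
                    {
                        "gene_id": genes,
                        "plate_id": [
                            f"{medium[:4]}-r{rep}-p{p:02d}" for p in plate_of_gene
                        ],
                        "row": pos_on_plate // n_cols + 1,
                        "col": pos_on_plate % n_cols + 1,
                        "replicate": rep,
                        "medium": medium,
                        "size_px": np.round(size).astype(float),
                    }
                )
            )
    plates = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_hit": is_hit,
            "planted_effect": effect,
            "is_dead": is_dead,
        }
    )
    return plates, truth


def simulate_presequence_set(
    n: int,
    length: int,
    background: dict[str, float] | None = None,
    planted: list[tuple[int, str, float]] | None = None,
    seed: int = 0,
    force: bool = False,
) -> list[SequenceRecord]:
    """Draw i.i.d. positional sequences with planted residue biases.

    Residues at unplanted positions follow ``background`` (default:
    yeast-like usage).  A planted ``(position, residue, fold)`` raises
    that residue's probability to min(1, fold × background) at that
    1-based position, renormalizing the remainder; ``force=True`` treats
    every planted fold as "probability 1".  Infeasible folds
    (fold × background > 1) are clamped with a warning.
    """
    import warnings

    background = dict(background or YEAST_AA_FREQS)
    if set(background) != set(AMINO_ACIDS):
        raise ValueError("background must cover exactly the 20 standard residues")
    total = sum(background.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("background frequencies must sum to 1")
    planted = planted or []
    for pos, res, fold in planted:
        if not 1 <= pos <= length:
            raise ValueError(f"planted position {pos} outside 1..{length}")
        if res not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {res!r}")
        if fold <= 0 and not force:
            raise ValueError("planted fold must be > 0")

    base = np.array([background[a] for a in AMINO_ACIDS])
    probs = np.tile(base, (length, 1))
    for pos, res, fold in planted:
        j = AMINO_ACIDS.index(res)
        if force or np.isinf(fold):
            target = 1.0
        else:
            target = fold * base[j]
            if target > 1.0:
                warnings.warn(
                    f"fold {fold} x background {base[j]:.3f} exceeds 1 at "
                    f"position {pos}; clamped",
                    stacklevel=2,
                )
                target = 1.0
        row = probs[pos - 1].copy()
        others = row.sum() - row[j]
        row = row * ((1.0 - target) / others if others > 0 else 0.0)
        row[j] = target
        probs[pos - 1] = row

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # inverse-CDF draw per position: u (n x length) against each
    # position's cumulative residue distribution
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n, length))
    idx = np.empty((n, length), dtype=int)
    for p in range(length):
        idx[:, p] = np.searchsorted(cum[p], u[:, p], side="right")
    letters = np.array(list(AMINO_ACIDS))
    return [
        SequenceRecord(id=f"seq{i:04d}", sequence="".join(letters[idx[i]]))
        for i in range(n)
    ]


def simulate_alignment(
    n_seqs: int,
    length: int,
    conserved_prefix: int,
    p_sub_conserved: float,
    p_sub_variable: float,
    seed: int = 0,
) -> tuple[list[SequenceRecord], str]:
    """Simulate a gapless protein alignment with a conserved N-terminal block.

    An ancestral sequence is drawn from uniform residue frequencies; each
    descendant substitutes every column independently, with probability
    ``p_sub_conserved`` in the first ``conserved_prefix`` columns and
    ``p_sub_variable`` elsewhere (substitutions draw uniformly from the
    19 other residues).  Returns the alignment and the ancestor.
    """
    if conserved_prefix > length:
        raise ValueError("conserved_prefix cannot exceed length")
    if p_sub_conserved > p_sub_variable:
        raise ValueError("conserved columns cannot be more variable than the rest")
    for p in (p_sub_conserved, p_sub_variable):
        if not 0.0 <= p <= 1.0:
            raise ValueError("substitution probabilities must be in [0, 1]")

    rng_anc, rng_desc = _spawn(seed, 2)
    letters = np.array(list(AMINO_ACIDS))
    ancestor = rng_anc.integers(0, 20, size=length)
    p_col = np.where(np.arange(length) < conserved_prefix, p_sub_conserved, p_sub_variable)

    records = []
    for i in range(n_seqs):
        seq = ancestor.copy()
        mutate = rng_desc.random(length) < p_col
        if mutate.any():
            # draw a uniform *different* residue at each mutated column
            shift = rng_desc.integers(1, 20, size=int(mutate.sum()))
            seq[mutate] = (seq[mutate] + shift) % 20
        records.append(
            SequenceRecord(id=f"sp{i:02d}", sequence="".join(letters[seq]))
        )
    return records, "".join(letters[ancestor])


def simulate_assay_series(
    kind: str, params: dict, seed: int = 0
) -> pd.DataFrame:
    """Simulate a bench-assay table consumable by :mod:`mitocpr.assays`.

    Kinds
    -----
    ``decay``
        Cycloheximide-chase intensities I(t) = I0 · 2^(−t/t_half) with
        multiplicative log-normal noise (``noise`` = CV); params:
        ``t_half`` (min), ``times``, ``n_replicates``, ``i0``.
    ``growth``
        Logistic OD curve od(t) = K·N0·e^{rt} / (K + N0·(e^{rt}−1))
        with multiplicative noise; params: ``r`` (per min), ``times``,
        ``n0``, ``k``.
    ``ct``
        A qPCR Ct table encoding a ``true_fold`` change of a target gene
        between control and experimental samples against a reference
        gene; params: ``true_fold``, ``dct_control``, ``ct_reference``,
        ``n_tech_reps``, ``noise`` (SD of per-well Ct jitter).
    ``fluorescence``
        A dye-quench membrane-potential trace: baseline plateau, quench
        drop after mitochondria addition at ``t_add`` (s), recovery after
        uncoupler at ``t_uncouple``; params: ``quench_depth``,
        ``duration_s``, ``interval_s``, ``noise``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if kind == "decay":
        t_half = float(params["t_half"])
        if t_half <= 0:
            raise ValueError("t_half must be > 0")
        times = np.asarray(params.get("times", [0, 15, 30, 45, 60]), dtype=float)
        n_rep = int(params.get("n_replicates", 1))
        i0 = float(params.get("i0", 1.0))
        noise = float(params.get("noise", 0.0))
        rows = []
        for rep in range(1, n_rep + 1):
            ideal = i0 * np.power(2.0, -times / t_half)
            if noise > 0:
                sd = np.sqrt(np.log1p(noise**2))
                ideal = ideal * np.exp(rng.normal(0.0, sd, times.size))
            rows.append(
                pd.DataFrame(
                    {"replicate": rep, "time_min": times, "intensity": ideal}
                )
            )
        return pd.concat(rows, ignore_index=True)

    if kind == "growth":
        r = float(params["r"])
        if r < 0:
            raise ValueError("growth rate must be >= 0")
        times = np.asarray(
            params.get("times", np.arange(0.0, 48 * 60 + 1, 15.0)), dtype=float
        )
        n0 = float(params.get("n0", 0.02))
        k = float(params.get("k", 1.0))
        noise = float(params.get("noise", 0.0))
        ert = np.exp(r * times)
        od = k * n0 * ert / (k + n0 * (ert - 1.0))
        if noise > 0:
            sd = np.sqrt(np.log1p(noise**2))
            od = od * np.exp(rng.normal(0.0, sd, times.size))
        return pd.DataFrame({"time_min": times, "od": od})

    if kind == "ct":
        true_fold = float(params["true_fold"])
        if true_fold <= 0:
            raise ValueError("true_fold must be > 0")
        dct_control = float(params.get("dct_control", 7.0))
        ct_ref = float(params.get("ct_reference", 18.0))
        n_tech = int(params.get("n_tech_reps", 3))
        noise = float(params.get("noise", 0.0))
        # fold = 2^-(dCt_exp - dCt_ctrl)  =>  dCt_exp = dCt_ctrl - log2(fold)
        dct_exp = dct_control - np.log2(true_fold)
        rows = []
        for sample, dct in (("control", dct_control), ("experimental", dct_exp)):
            for gene, ct in (("target", ct_ref + dct), ("reference", ct_ref)):
                for tech in range(1, n_tech + 1):
                    rows.append(
                        {
                            "sample": sample,
                            "condition": sample,
                            "gene": gene,
                            "ct": ct + (rng.normal(0.0, noise) if noise > 0 else 0.0),
                            "tech_rep": tech,
                        }
                    )
        return pd.DataFrame(rows)

    if kind == "fluorescence":
        depth = float(params.get("quench_depth", 0.4))
        if not 0.0 < depth <= 1.0:
            raise ValueError("quench_depth must be in (0, 1]")
        duration = float(params.get("duration_s", 360.0))
        interval = float(params.get("interval_s", 5.0))
        t_add = float(params.get("t_add", 90.0))
        t_unc = float(params.get("t_uncouple", t_add + 180.0))
        noise = float(params.get("noise", 0.0))
        times = np.arange(0.0, duration + interval / 2, interval)
        f = np.ones_like(times)
        tau = 15.0  # quench relaxation time constant, seconds
        after_add = times >= t_add
        f[after_add] = depth + (1 - depth) * np.exp(-(times[after_add] - t_add) / tau)
        after_unc = times >= t_unc
        quenched = depth + (1 - depth) * np.exp(-(t_unc - t_add) / tau)
        f[after_unc] = 1.0 + (quenched - 1.0) * np.exp(-(times[after_unc] - t_unc) / tau)
        if noise > 0:
            f = f * (1.0 + rng.normal(0.0, noise, times.size))
        return pd.DataFrame({"time_s": times, "fluorescence": f * 100.0})

    raise ValueError(f"unknown assay kind {kind!r}")
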