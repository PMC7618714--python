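"""Colony-array overexpression-screen scoring.

The pipeline mirrors how arrayed reporter screens are scored from colony
pixel densities: dead colonies are excluded on the permissive (control)
medium, plate-to-plate variation is removed by normalizing every plate
to the grand average of its treatment group, colony sizes are Z-scored
against the treatment-group distribution, and genes are ranked by the
mean Z-score difference between selective and permissive media with
FDR-controlled hit calling.

Treatment groups are the two media: colonies grown on the selective
medium (reporter-driven growth) form one group, colonies on the
permissive medium the other.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mitocpr.io import MEDIA

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE_PX = 20.0
DEFAULT_Q_THRESHOLD = 0.05


class DegenerateScreenError(ValueError):
    """Raised when a treatment group has zero variance."""


def filter_small_colonies(
    plates: pd.DataFrame, min_size_px: float = DEFAULT_MIN_SIZE_PX
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop dead/sick strains from both media.

    A gene is removed entirely when its mean colony size on the
    permissive medium is strictly below ``min_size_px``, or when it has
    no permissive-medium measurement at all ("no control growth").

    Returns
    -------
    (surviving, excluded)
        ``surviving`` is the subset of ``plates``; ``excluded`` reports
        one row per removed gene with the reason.
    """
    perm = plates[plates["medium"] == "permissive"]
    mean_perm = perm.groupby("gene_id")["size_px"].mean()

    all_genes = pd.Index(sorted(plates["gene_id"].unique()))
    reasons = {}
    for gene in all_genes:
        if gene not in mean_perm.index:
            reasons[gene] = "no control growth"
        elif mean_perm[gene] < min_size_px:
            reasons[gene] = f"mean permissive size {mean_perm[gene]:g} < {min_size_px:g}"
    excluded = pd.DataFrame(
        {"gene_id": list(reasons), "reason": list(reasons.values())}
    )
    surviving = plates[~plates["gene_id"].isin(reasons)].copy()
    return surviving, excluded


def normalize_plates(plates: pd.DataFrame) -> pd.DataFrame:
    """Normalize colony sizes to the grand average of each treatment group.

    Every plate's sizes are rescaled by (grand mean of plate means within
    the plate's medium group) / (own plate mean), so that after
    normalization each plate's mean equals the group grand mean.

    Returns the input plus ``size_norm`` and ``group_grand_mean`` columns.
    """
    out = plates.copy()
    out["size_norm"] = np.nan
    out["group_grand_mean"] = np.nan
    for medium in MEDIA:
        mask = out["medium"] == medium
        if not mask.any():
            continue
        sub = out.loc[mask]
        plate_means = sub.groupby("plate_id")["size_px"].mean()
        if (plate_means <= 0).any():
            bad = plate_means.index[plate_means <= 0][0]
            raise ValueError(f"plate {bad!r} ({medium}) has non-positive mean size")
        grand = plate_means.mean()
        factors = grand / plate_means
        out.loc[mask, "size_norm"] = sub["size_px"].to_numpy() * factors.loc[
            sub["plate_id"]
        ].to_numpy()
        out.loc[mask, "group_grand_mean"] = grand
    return out


def gene_zscores(norm: pd.DataFrame, medium: str) -> pd.DataFrame:
    """Z-score normalized sizes against the treatment-group distribution.

    Each measurement on ``medium`` is standardized against the mean and
    sample standard deviation (n-1 denominator) of *all* normalized sizes
    in that medium's group; the per-gene score is the mean over its
    replicates.

    Returns a frame indexed by gene with ``mean_z``, ``n_replicates``,
    and a ``replicate_zs`` object column (numpy arrays).
    """
    if medium not in MEDIA:
        raise ValueError(f"unknown medium {medium!r}")
    if "size_norm" not in norm.columns:
        raise ValueError("normalize_plates must run before gene_zscores")
    sub = norm[norm["medium"] == medium]
    values = sub["size_norm"].to_numpy(dtype=float)
    sd = values.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DegenerateScreenError(f"degenerate screen: zero variance on {medium}")
    z = (values - values.mean()) / sd
    frame = pd.DataFrame({"gene_id": sub["gene_id"].to_numpy(), "z": z})
    grouped = frame.groupby("gene_id")["z"]
    out = pd.DataFrame(
        {
            "mean_z": grouped.mean(),
            "n_replicates": grouped.size(),
            "replicate_zs": grouped.apply(lambda s: s.to_numpy()),
        }
    )
    out.index.name = "gene_id"
    return out


def storey_qvalues(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the single-lambda plug-in estimate of pi0.

    pi0 = #{p > lambda} / (m * (1 - lambda)), clamped to (0, 1]; q-values
    are the usual step-up running minimum of pi0 * m * p / rank.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    pi0 = (p > lam).sum() / (m * (1.0 - lam))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def _pvalues(table: pd.DataFrame, test: str) -> np.ndarray:
    """One-sided p-values for selective > permissive per gene."""
    pvals = np.empty(len(table))
    for i, row in enumerate(table.itertuples(index=False)):
        zs, zp = row.zs_sel, row.zs_perm
        n1, n2 = len(zs), len(zp)
        if test == "welch" and min(n1, n2) >= 2:
            res = stats.ttest_ind(zs, zp, equal_var=False, alternative="greater")
            pvals[i] = res.pvalue
        else:
            if test == "welch":
                logger.info(
                    "gene %s: <2 replicates on a medium; normal-tail fallback",
                    row.gene_id,
                )
            # replicate Z-scores have unit variance by construction, so the
            # mean difference has known variance 1/n1 + 1/n2
            stat = (zs.mean() - zp.mean()) / np.sqrt(1.0 / n1 + 1.0 / n2)
            pvals[i] = stats.norm.sf(stat)
    return pvals


def score_hits(
    norm: pd.DataFrame,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    fdr: str = "storey",
    test: str = "normal",
    min_genes_for_storey: int = 100,
) -> pd.DataFrame:
    """Build the ranked hit table from a normalized screen.

    Per gene: ``z_diff`` = mean selective Z minus mean permissive Z; a
    one-sided p-value for selective > permissive (``test="normal"``: the
    unit-variance normal test on the mean Z difference, exact because
    replicate Z-scores are standardized group-wide; ``test="welch"``:
    Welch's t on the replicate Z-scores); q-values by Storey's lambda=0.5
    plug-in (``fdr="storey"``, falling back to Benjamini-Hochberg below
    ``min_genes_for_storey`` genes) or BH (``fdr="bh"``).  Hits are the
    genes with q below ``q_threshold``, ranked by z_diff descending with
    ties broken by smaller q then gene_id.
    """
    if fdr not in ("storey", "bh"):
        raise ValueError(f"unknown fdr procedure {fdr!r}")
    if test not in ("normal", "welch"):
        raise ValueError(f"unknown test {test!r}")

    sel = gene_zscores(norm, "selective")
    perm = gene_zscores(norm, "permissive")
    common = sel.index.intersection(perm.index)
    dropped = sel.index.symmetric_difference(perm.index)
    if len(dropped):
        logger.info("dropping %d gene(s) present in only one group", len(dropped))

    table = pd.DataFrame(
        {
            "gene_id": common,
            "z_selective": sel.loc[common, "mean_z"].to_numpy(),
            "z_permissive": perm.loc[common, "mean_z"].to_numpy(),
            "zs_sel": sel.loc[common, "replicate_zs"].to_numpy(),
            "zs_perm": perm.loc[common, "replicate_zs"].to_numpy(),
        }
    )
    table["z_diff"] = table["z_selective"] - table["z_permissive"]
    table["p_value"] = _pvalues(table, test)

    if fdr == "storey" and len(table) >= min_genes_for_storey:
        table["q_value"] = storey_qvalues(table["p_value"].to_numpy())
    else:
        if fdr == "storey":
            logger.info(
                "fewer than %d genes: Benjamini-Hochberg instead of Storey",
                min_genes_for_storey,
            )
        table["q_value"] = multipletests(
            table["p_value"].to_numpy(), method="fdr_bh"
        )[1]

    table["is_hit"] = table["q_value"] < q_threshold
    table = table.sort_values(
        by=["is_hit", "z_diff", "q_value", "gene_id"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table[
        [
            "gene_id",
            "z_selective",
            "z_permissive",
            "z_diff",
            "p_value",
            "q_value",
            "rank",
            "is_hit",
        ]
    ]


def run_screen(
    plates: pd.DataFrame,
    min_size_px: float = DEFAULT_MIN_SIZE_PX,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    fdr: str = "storey",
    test: str = "normal",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scoring pipeline: filter, normalize, score.

    Returns (hit table, exclusion report).
    """
    surviving, excluded = filter_small_colonies(plates, min_size_px)
    if surviving.empty:
        raise ValueError("no genes survive the dead-colony filter")
    norm = normalize_plates(surviving)
    hits = score_hits(norm, q_threshold=q_threshold, fdr=fdr, test=test)
    return hits, excluded
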