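"""Bench-assay arithmetic.

Implements the quantification steps that accompany a yeast
import-stress study:

* qPCR relative expression by the 2^-ddCt method (amplification
  efficiency fixed at 2),
* ChIP enrichment with input correction and normalization to a silent
  control locus (HMR),
* cycloheximide-chase half-lives by log-linear least squares,
* exponential growth constants from the max-R² window of ln(OD),
* membrane-potential indices from dye-quench fluorescence traces,
* import-kinetics normalization to the control series' final point.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


# ---------------------------------------------------------------- qPCR


@dataclasses.dataclass(frozen=True)
class FoldChangeResult:
    sample: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


def ddct_fold_change(
    ct: pd.DataFrame, reference_gene: str = "ACT1", control_sample: str = "control"
) -> list[FoldChangeResult]:
    """Relative expression of every (sample, target gene) by 2^-ddCt.

    Technical replicates are averaged first (arithmetic mean of Ct);
    dCt = Ct_target − Ct_reference per sample; ddCt = dCt_sample −
    dCt_control; fold change = 2^−ddCt.  The control sample's own fold
    change is exactly 1.
    """
    required = {"sample", "gene", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    mean_ct = ct.groupby(["sample", "gene"])["ct"].mean()

    samples = mean_ct.index.get_level_values("sample").unique()
    if control_sample not in samples:
        raise ValueError(f"control sample {control_sample!r} absent from table")

    def dct(sample: str, gene: str) -> float:
        if (sample, reference_gene) not in mean_ct.index:
            raise ValueError(
                f"reference gene {reference_gene!r} missing for sample {sample!r}"
            )
        return mean_ct[(sample, gene)] - mean_ct[(sample, reference_gene)]

    out = []
    for sample, gene in mean_ct.index:
        if gene == reference_gene:
            continue
        d = dct(sample, gene)
        dd = d - dct(control_sample, gene)
        out.append(
            FoldChangeResult(
                sample=sample,
                gene=gene,
                delta_ct=float(d),
                delta_delta_ct=float(dd),
                fold_change=float(2.0 ** (-dd)),
            )
        )
    return out


def fold_change_table(results: list[FoldChangeResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


# ---------------------------------------------------------------- ChIP


def chip_enrichment(
    ip_signal: float,
    input_signal: float,
    ip_norm_locus: float,
    input_norm_locus: float,
) -> float:
    """Input-corrected ChIP signal normalized to a control locus.

    ``(IP_target / input_target) / (IP_HMR / input_HMR)``; all four
    signals must be positive.
    """
    for name, v in (
        ("ip_signal", ip_signal),
        ("input_signal", input_signal),
        ("ip_norm_locus", ip_norm_locus),
        ("input_norm_locus", input_norm_locus),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0 (got {v})")
    return (ip_signal / input_signal) / (ip_norm_locus / input_norm_locus)


# ----------------------------------------------------------- half-life


@dataclasses.dataclass(frozen=True)
class HalfLifeEstimate:
    t_half: float  # minutes; inf when no decay
    slope: float  # per minute, on ln(intensity)
    intercept: float
    r_squared: float
    n_points: int

    @property
    def decays(self) -> bool:
        return np.isfinite(self.t_half)


def half_life(
    series: pd.DataFrame | list[tuple[float, float]],
    min_points: int = 3,
    normalize_t0: bool = True,
) -> HalfLifeEstimate:
    """Protein half-life from a translation-shutoff decay series.

    Ordinary least squares of ln(intensity) on time; t½ = ln 2 / (−slope)
    for negative slopes, infinite-decay flag otherwise.  A ``replicate``
    column fits all replicates jointly by pooling points, each replicate
    pre-normalized to its own t=0 intensity when ``normalize_t0``.
    Non-positive intensities are excluded with a warning.
    """
    df = _as_series_frame(series, "time_min", "intensity")
    if "replicate" not in df.columns:
        df = df.assign(replicate=1)

    pos = df["intensity"] > 0
    if (~pos).any():
        logger.warning("excluding %d non-positive intensities", int((~pos).sum()))
        df = df[pos]
    if len(df) < min_points:
        raise ValueError(f"fewer than {min_points} usable points")

    parts = []
    for _, grp in df.groupby("replicate"):
        grp = grp.sort_values("time_min")
        y = grp["intensity"].to_numpy(dtype=float)
        if normalize_t0:
            y = y / y[0]
        parts.append(np.column_stack([grp["time_min"].to_numpy(dtype=float), y]))
    pooled = np.vstack(parts)
    t, y = pooled[:, 0], np.log(pooled[:, 1])
    if np.unique(t).size < 2:
        raise ValueError("need at least two distinct time points")

    fit = stats.linregress(t, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue**2)
    t_half = LN2 / (-slope) if slope < 0 else float("inf")
    return HalfLifeEstimate(
        t_half=t_half, slope=slope, intercept=intercept, r_squared=r2,
        n_points=len(pooled),
    )


# ---------------------------------------------------------- growth rate


@dataclasses.dataclass(frozen=True)
class GrowthRateResult:
    r_per_min: float
    window_start_idx: int  # 0-based index into the sorted curve
    window_len: int
    r_squared: float
    exponential_phase_found: bool


def growth_rate(
    curve: pd.DataFrame | list[tuple[float, float]],
    window: int = 9,
    min_r_squared: float = 0.99,
) -> GrowthRateResult:
    """Exponential growth constant from an OD time course.

    ln(OD) is fitted linearly over every contiguous window of ``window``
    points (clipped to the curve length, never below 5); r is the slope
    of the steepest window whose fit satisfies ``R² >= min_r_squared`` —
    the maximum specific growth rate, which sidesteps the downward bias
    of fitting into the deceleration phase.  If no window passes the
    linearity guard, the steepest positive-slope window is used anyway
    (its R² is reported); if no window has positive slope at all, r = 0
    with ``exponential_phase_found=False``.
    """
    df = _as_series_frame(curve, "time_min", "od").sort_values("time_min")
    if len(df) < 5:
        raise ValueError("need at least 5 points")
    if (df["od"] <= 0).any():
        raise ValueError("OD values must be > 0")

    t = df["time_min"].to_numpy(dtype=float)
    y = np.log(df["od"].to_numpy(dtype=float))
    n = t.size
    w = max(5, min(window, n))

    best_guarded = None  # (slope, start, r2)
    best_any = None
    for start in range(0, n - w + 1):
        fit = stats.linregress(t[start : start + w], y[start : start + w])
        if not fit.slope > 0:
            continue
        r2 = float(fit.rvalue**2)
        cand = (float(fit.slope), start, r2)
        if best_any is None or cand[0] > best_any[0]:
            best_any = cand
        if r2 >= min_r_squared and (
            best_guarded is None or cand[0] > best_guarded[0]
        ):
            best_guarded = cand
    if best_any is None:
        return GrowthRateResult(0.0, 0, 0, 0.0, False)
    if best_guarded is None:
        logger.warning(
            "no window reached R^2 >= %g; using steepest window", min_r_squared
        )
        best_guarded = best_any
    slope, start, r2 = best_guarded
    return GrowthRateResult(
        r_per_min=slope,
        window_start_idx=start,
        window_len=w,
        r_squared=r2,
        exponential_phase_found=True,
    )


# --------------------------------------------- membrane potential index


def membrane_potential_index(
    trace: pd.DataFrame | list[tuple[float, float]],
    window_start: float,
    window_len_s: float = 180.0,
) -> tuple[pd.DataFrame, float]:
    """Normalized dye-quench trace and its quantification window mean.

    Fluorescence is normalized to the maximum of the individual trace;
    the index is the mean normalized signal over
    [window_start, window_start + window_len_s] — by convention the
    3-minute window following mitochondria addition, where a polarized
    membrane quenches the dye.
    """
    df = _as_series_frame(trace, "time_s", "fluorescence").sort_values("time_s")
    peak = df["fluorescence"].max()
    if not peak > 0:
        raise ValueError("trace maximum must be > 0")
    out = df.assign(normalized=df["fluorescence"] / peak)
    in_window = (out["time_s"] >= window_start) & (
        out["time_s"] <= window_start + window_len_s
    )
    if not in_window.any():
        raise ValueError("no points inside the quantification window")
    return out, float(out.loc[in_window, "normalized"].mean())


# ------------------------------------------------------ import kinetics


def normalize_import_kinetics(
    control_series: pd.DataFrame | list[tuple[float, float]],
    test_series: pd.DataFrame | list[tuple[float, float]],
) -> pd.DataFrame:
    """Express paired import time courses as percent of control endpoint.

    Both series must share their time grid; every value is divided by
    the control series' final-time value and multiplied by 100, so the
    control endpoint is exactly 100%.
    """
    ctrl = _as_series_frame(control_series, "time_min", "signal").sort_values("time_min")
    test = _as_series_frame(test_series, "time_min", "signal").sort_values("time_min")
    if not np.array_equal(ctrl["time_min"].to_numpy(), test["time_min"].to_numpy()):
        raise ValueError("control and test series must share time points")
    final = float(ctrl["signal"].iloc[-1])
    if final <= 0:
        raise ValueError("control final value must be > 0")
    return pd.DataFrame(
        {
            "time_min": ctrl["time_min"].to_numpy(),
            "control_pct": ctrl["signal"].to_numpy() / final * 100.0,
            "test_pct": test["signal"].to_numpy() / final * 100.0,
        }
    )


# ------------------------------------------------------------- helpers


def _as_series_frame(obj, time_col: str, value_col: str) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        cols = set(obj.columns)
        if time_col not in cols:
            raise ValueError(f"missing column {time_col!r}")
        if value_col not in cols:
            # accept the simulator's column names for the same quantity
            aliases = {"intensity", "od", "fluorescence", "signal"}
            found = aliases & cols
            if len(found) == 1:
                obj = obj.rename(columns={found.pop(): value_col})
            else:
                raise ValueError(f"missing column {value_col!r}")
        return obj.copy()
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be (time, value) pairs")
    return pd.DataFrame({time_col: arr[:, 0], value_col: arr[:, 1]})
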