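"""Hypothesis tests, the three-criterion marker-lipid caller, and qPCR ddCt.

A lipid is a marker for a comparison when all three hold: fold change
above 1.5 or below 0.667, Bonferroni-adjusted Welch p-value below alpha,
and non-overlapping interquartile ranges of the two groups.  When a
cluster is compared against a set of clusters, the set is pooled with one
data point per cell, so larger clusters weigh more.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonSpec",
    "paired_t_test",
    "two_sample_t_test",
    "bonferroni_adjust",
    "iqr_overlap",
    "find_markers",
    "paired_feature_tests",
    "ddct_fold_change",
]


@dataclass
class ComparisonSpec:
    """Marker comparison settings: group masks, thresholds, significance tier."""

    group_a: np.ndarray  # boolean mask over units
    group_b: np.ndarray
    alpha: float = 0.01
    fc_high: float = 1.5
    fc_low: float = 0.667
    strict_alpha: float = 0.001  # reported significance tier for highlighting
    name: str = "A_vs_B"

    def __post_init__(self) -> None:
        self.group_a = np.asarray(self.group_a, dtype=bool)
        self.group_b = np.asarray(self.group_b, dtype=bool)
        if not self.fc_low < 1.0 < self.fc_high:
            raise ValueError("need fc_low < 1 < fc_high")
        if (self.group_a & self.group_b).any():
            raise ValueError("groups must be disjoint")


def paired_t_test(x, y):
    """Two-sided paired t-test (one-sample t on differences).

    Returns ``(t, df, p)``; zero-variance differences give ``(nan, df,
    nan)`` with a warning, except the all-zero case where t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired vectors must have equal length >= 2")
    d = x - y
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, df, 1.0
        warnings.warn("zero-variance nonzero differences: p undefined")
        return float("nan"), df, float("nan")
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def two_sample_t_test(x, y, equal_var: bool = False):
    """Two-sided two-sample t-test, Welch by default. Returns ``(t, df, p)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        return float("inf") * np.sign(x.mean() - y.mean()), float(x.size + y.size - 2), 0.0
    if equal_var:
        nx, ny = x.size, y.size
        df = nx + ny - 2
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    else:
        nx, ny = x.size, y.size
        se2 = vx / nx + vy / ny
        t = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bonferroni_adjust(p) -> np.ndarray:
    """p_adj = min(1, p * m) over the m tests supplied."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


def iqr_overlap(x, y) -> bool:
    """Do the [Q1, Q3] intervals of x and y intersect? (quantile type 7)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4 or y.size < 4:
        raise ValueError("each group needs >= 4 observations for IQR")
    q1x, q3x = np.quantile(x, [0.25, 0.75])
    q1y, q3y = np.quantile(y, [0.25, 0.75])
    return bool(max(q1x, q1y) <= min(q3x, q3y))


# ---------------------------------------------------------------------------


def find_markers(values: pd.DataFrame, spec: ComparisonSpec) -> pd.DataFrame:
    """Three-criterion marker table for group A vs group B.

    ``values`` must be on the unscaled (normalized, batch-corrected,
    back-transformed) intensity scale: fold changes are ratios of linear
    means.  The Welch test runs per feature with Bonferroni adjustment
    over the tested features; all three criteria apply conjunctively.
    """
    a_mask, b_mask = spec.group_a, spec.group_b
    if a_mask.sum() < 4 or b_mask.sum() < 4:
        raise ValueError("both groups need >= 4 cells after pooling")
    A = values.to_numpy(float)[a_mask]
    B = values.to_numpy(float)[b_mask]
    recs = []
    for j, feat in enumerate(values.columns):
        mean_a, mean_b = A[:, j].mean(), B[:, j].mean()
        fc = mean_a / mean_b if mean_b > 0 else np.inf
        t, df, p = two_sample_t_test(A[:, j], B[:, j])
        recs.append(
            {
                "feature": feat,
                "mean_A": mean_a,
                "mean_B": mean_b,
                "fold_change": fc,
                "t_stat": t,
                "df": df,
                "p_raw": p,
                "iqr_overlap": iqr_overlap(A[:, j], B[:, j]),
            }
        )
    out = pd.DataFrame(recs).set_index("feature")
    out["p_adj"] = bonferroni_adjust(np.nan_to_num(out["p_raw"].to_numpy(), nan=1.0))
    fc_ok = (out["fold_change"] > spec.fc_high) | (out["fold_change"] < spec.fc_low)
    out["is_marker"] = fc_ok & (out["p_adj"] < spec.alpha) & ~out["iqr_overlap"]
    out["strict"] = out["is_marker"] & (out["p_adj"] < spec.strict_alpha)
    out["direction"] = np.where(out["fold_change"] > 1.0, "up", "down")
    out.attrs["comparison"] = spec.name
    return out


def paired_feature_tests(values: pd.DataFrame, obs: pd.DataFrame, group_key: str,
                         pair_key: str = "pair_id") -> pd.DataFrame:
    """Per-feature paired t-tests between the two levels of ``group_key``.

    Units are paired by ``pair_key`` (e.g. matrix-application round or the
    source sample); p-values are Bonferroni-adjusted over features.  Used
    for the whole-sample treatment comparison and the cohesive-vs-dispersed
    comparison.
    """
    levels = list(pd.unique(obs[group_key]))
    if len(levels) != 2:
        raise ValueError(f"{group_key} must have exactly two levels, got {levels}")
    la, lb = levels
    pairs = []
    for pid in pd.unique(obs[pair_key]):
        sel = obs[pair_key] == pid
        ia = obs.index[sel & (obs[group_key] == la)]
        ib = obs.index[sel & (obs[group_key] == lb)]
        if len(ia) == 1 and len(ib) == 1:
            pairs.append((ia[0], ib[0]))
        else:
            logger.warning("pair %r skipped: needs one unit per level", pid)
    if len(pairs) < 2:
        raise ValueError("need >= 2 complete pairs")
    A = values.loc[[p[0] for p in pairs]].to_numpy(float)
    B = values.loc[[p[1] for p in pairs]].to_numpy(float)
    recs = []
    for j, feat in enumerate(values.columns):
        t, df, p = paired_t_test(A[:, j], B[:, j])
        mean_a, mean_b = A[:, j].mean(), B[:, j].mean()
        recs.append(
            {
                "feature": feat,
                f"mean_{la}": mean_a,
                f"mean_{lb}": mean_b,
                "fold_change": mean_a / mean_b if mean_b > 0 else np.inf,
                "t_stat": t,
                "df": df,
                "p_raw": p,
            }
        )
    out = pd.DataFrame(recs).set_index("feature")
    out["p_adj"] = bonferroni_adjust(np.nan_to_num(out["p_raw"].to_numpy(), nan=1.0))
    out["significant"] = out["p_adj"] < 0.05
    return out


# ---------------------------------------------------------------------------


def ddct_fold_change(
    ct: pd.DataFrame,
    sample_groups: pd.Series,
    reference_gene: str,
    control_group: str,
) -> pd.DataFrame:
    """Relative expression by the delta-delta-Ct method with pairwise tests.

    ``ct`` is genes x samples of Ct values; ``sample_groups`` maps sample
    to treatment group (e.g. stimulation time).  Per sample, dCt =
    Ct_target - Ct_reference; ddCt = mean dCt(group) - mean dCt(control);
    fold change = 2^(-ddCt).  Each non-control group is compared to the
    control with a two-sample t-test on dCt, Bonferroni-adjusted over the
    number of compared groups.  Samples missing the reference Ct are
    dropped with a warning.
    """
    if reference_gene not in ct.index:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    ref = ct.loc[reference_gene]
    missing = ref.isna()
    if missing.any():
        warnings.warn(f"dropping samples without reference Ct: {list(ct.columns[missing])}")
        ct = ct.loc[:, ~missing]
        ref = ref[~missing]
    sample_groups = sample_groups.loc[ct.columns]
    groups = [g for g in pd.unique(sample_groups) if g != control_group]
    if control_group not in set(sample_groups):
        raise ValueError(f"control group {control_group!r} absent")
    dct = ct.drop(index=reference_gene).sub(ref, axis=1)
    ctrl_cols = sample_groups.index[sample_groups == control_group]
    recs = []
    for gene in dct.index:
        d_ctrl = dct.loc[gene, ctrl_cols].to_numpy(float)
        for grp in groups:
            cols = sample_groups.index[sample_groups == grp]
            d_grp = dct.loc[gene, cols].to_numpy(float)
            ddct = d_grp.mean() - d_ctrl.mean()
            if d_grp.size >= 2 and d_ctrl.size >= 2:
                t, df, p = two_sample_t_test(d_grp, d_ctrl)
            else:
                t, df, p = np.nan, np.nan, np.nan
            recs.append(
                {
                    "gene": gene,
                    "group": grp,
                    "ddct": ddct,
                    "fold_change": 2.0 ** (-ddct),
                    "t_stat": t,
                    "p_raw": p,
                }
            )
    out = pd.DataFrame(recs)
    out["p_adj"] = np.nan
    for gene in dct.index:
        sel = out["gene"] == gene
        p = np.nan_to_num(out.loc[sel, "p_raw"].to_numpy(float), nan=1.0)
        out.loc[sel, "p_adj"] = bonferroni_adjust(p)
    return out.set_index(["gene", "group"])
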