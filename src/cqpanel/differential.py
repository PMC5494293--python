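"""Per-miRNA two-group statistics on delta-Cq values.

The effect size is the between-group difference of mean delta-Cq,
``ddcq = mean(periodontitis) - mean(healthy)``.  Because a lower Cq
means higher abundance, the sign-flipped quantity ``neg_ddcq = -ddcq``
is the log2-scale relative expression ratio: positive values are
up-regulated in the periodontitis group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GROUPS, MirnaList, SampleSheet
from .normalization import NormalizedTable

__all__ = [
    "GroupEffect",
    "DiffExpTable",
    "group_effect",
    "two_sample_t",
    "bh_adjust",
    "differential_table",
    "select_candidates",
    "read_diff_table",
    "write_diff_table",
]

T_VARIANTS = ("welch", "student")


@dataclass(frozen=True)
class GroupEffect:
    """Group means and effect size for one miRNA."""

    n_healthy: int
    n_perio: int
    mean_dcq_h: float
    mean_dcq_p: float
    ddcq: float
    neg_ddcq: float
    direction: str  # "up" | "down" | "none"
    analyzable: bool


def _direction(neg_ddcq: float) -> str:
    if np.isnan(neg_ddcq) or neg_ddcq == 0:
        return "none"
    return "up" if neg_ddcq > 0 else "down"


def group_effect(dcq_h: Sequence[float], dcq_p: Sequence[float]) -> GroupEffect:
    """Compute group means and the (signed) delta-delta-Cq effect.

    Means are taken over detected (non-missing) values only.  If either
    group has no detected value the record is flagged not analyzable and
    all statistics are missing.
    """
    h = np.asarray(dcq_h, dtype=float)
    p = np.asarray(dcq_p, dtype=float)
    h = h[~np.isnan(h)]
    p = p[~np.isnan(p)]
    if h.size == 0 or p.size == 0:
        return GroupEffect(h.size, p.size, np.nan, np.nan, np.nan, np.nan, "none", False)
    mh, mp = float(h.mean()), float(p.mean())
    ddcq = mp - mh
    return GroupEffect(h.size, p.size, mh, mp, ddcq, -ddcq, _direction(-ddcq), True)


def two_sample_t(
    dcq_h: Sequence[float],
    dcq_p: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float]:
    """Two-sided two-sample t test on detected values; returns (t, p).

    ``variant`` selects Welch (unequal variances) or Student (pooled
    variance).  Degenerate inputs are handled explicitly: fewer than two
    detected values in a group, or two zero-variance groups with equal
    means, give ``(nan, nan)``; zero variance in both groups with
    unequal means gives a signed infinite t and p = 0 with a warning.
    """
    if variant not in T_VARIANTS:
        raise ValueError(f"unknown t variant {variant!r}; expected one of {T_VARIANTS}")
    h = np.asarray(dcq_h, dtype=float)
    p = np.asarray(dcq_p, dtype=float)
    h = h[~np.isnan(h)]
    p = p[~np.isnan(p)]
    if h.size < 2 or p.size < 2:
        return (np.nan, np.nan)
    vh, vp = h.var(ddof=1), p.var(ddof=1)
    if vh == 0 and vp == 0:
        if h.mean() == p.mean():
            return (np.nan, np.nan)
        warnings.warn(
            "zero variance in both groups with unequal means; "
            "p reported as the limiting value 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return (np.sign(h.mean() - p.mean()) * np.inf, 0.0)
    res = stats.ttest_ind(h, p, equal_var=(variant == "student"))
    return (float(res.statistic), float(res.pvalue))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q values.

    Missing p values are excluded from the procedure and returned
    missing; ``m`` is the count of non-missing entries.  q values are
    monotone in p rank and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    if pv.size == 0:
        return out
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    scaled = pv[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    out[mask] = q
    return out


@dataclass
class DiffExpTable:
    """Per-miRNA differential-expression records for one contrast.

    ``df`` is indexed by miRNA id with columns ``n_healthy, n_perio,
    mean_dcq_h, mean_dcq_p, ddcq, neg_ddcq, t_stat, p_value, q_value,
    direction, passes``, deterministically sorted by (q value, name).
    """

    df: pd.DataFrame
    set_id: str = ""
    method: str = ""
    t_variant: str = "welch"
    q_max: float = 0.05
    ddcq_min: float = 1.0

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.df.index)


_DIFF_COLUMNS = [
    "n_healthy",
    "n_perio",
    "mean_dcq_h",
    "mean_dcq_p",
    "ddcq",
    "neg_ddcq",
    "t_stat",
    "p_value",
    "q_value",
    "direction",
    "passes",
]


def differential_table(
    norm: NormalizedTable,
    sheet: SampleSheet,
    *,
    t_variant: str = "welch",
    q_max: float = 0.05,
    ddcq_min: float = 1.0,
    min_n: int = 2,
    set_id: str = "",
) -> DiffExpTable:
    """Two-group differential table over all miRNAs of a normalized matrix.

    Statistics use detected values only; miRNAs with fewer than
    ``min_n`` detected values in a group are reported descriptively
    (effect size without p/q).  BH adjustment runs over the tested
    miRNAs.  ``passes`` applies strict thresholds ``q < q_max`` and
    ``|ddcq| > ddcq_min``.
    """
    if t_variant not in T_VARIANTS:
        raise ValueError(f"unknown t variant {t_variant!r}")
    sub = sheet.restrict(norm.sample_ids)
    h_ids = sub.samples_in_group("healthy")
    p_ids = sub.samples_in_group("periodontitis")
    if not h_ids or not p_ids:
        raise ValueError("both groups must be present among the samples")

    H = norm.delta_cq[h_ids].to_numpy()
    P = norm.delta_cq[p_ids].to_numpy()
    nh = (~np.isnan(H)).sum(axis=1)
    np_ = (~np.isnan(P)).sum(axis=1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mh = np.nanmean(np.where(np.isnan(H), np.nan, H), axis=1)
        mp = np.nanmean(np.where(np.isnan(P), np.nan, P), axis=1)
    mh = np.where(nh > 0, mh, np.nan)
    mp = np.where(np_ > 0, mp, np.nan)
    ddcq = mp - mh

    t_stat = np.full(len(norm.mirna_ids), np.nan)
    p_val = np.full(len(norm.mirna_ids), np.nan)
    testable = (nh >= min_n) & (np_ >= min_n)

    complete = testable & ~np.isnan(H).any(axis=1) & ~np.isnan(P).any(axis=1)
    if complete.any():
        a, b = H[complete], P[complete]
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        ok = (va > 0) | (vb > 0)
        if ok.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(
                    a[ok], b[ok], axis=1, equal_var=(t_variant == "student")
                )
            ti = np.where(complete)[0][ok]
            t_stat[ti] = res.statistic
            p_val[ti] = res.pvalue
        degenerate = np.where(complete)[0][~ok]
    else:
        degenerate = np.array([], dtype=int)

    ragged = np.where(testable & ~complete)[0]
    for i in np.concatenate([ragged, degenerate]).astype(int):
        t_stat[i], p_val[i] = two_sample_t(H[i], P[i], variant=t_variant)

    q_val = bh_adjust(p_val)
    neg = -ddcq
    direction = np.where(
        np.isnan(neg) | (neg == 0), "none", np.where(neg > 0, "up", "down")
    )
    passes = (q_val < q_max) & (np.abs(ddcq) > ddcq_min)
    passes &= ~np.isnan(q_val)

    df = pd.DataFrame(
        {
            "n_healthy": nh,
            "n_perio": np_,
            "mean_dcq_h": mh,
            "mean_dcq_p": mp,
            "ddcq": ddcq,
            "neg_ddcq": neg,
            "t_stat": t_stat,
            "p_value": p_val,
            "q_value": q_val,
            "direction": direction,
            "passes": passes,
        },
        index=pd.Index(norm.mirna_ids, name="mirna_id"),
    )
    df = df.sort_values(
        ["q_value", "mirna_id"], na_position="last", kind="mergesort"
    )
    return DiffExpTable(
        df[_DIFF_COLUMNS],
        set_id=set_id,
        method=norm.method,
        t_variant=t_variant,
        q_max=q_max,
        ddcq_min=ddcq_min,
    )


def select_candidates(
    table: DiffExpTable, q_max: float = 0.05, ddcq_min: float = 1.0
) -> tuple[MirnaList, MirnaList]:
    """Split significant, large-effect miRNAs into up/down candidate lists.

    Strict thresholds: ``q < q_max`` and ``|neg_ddcq| > ddcq_min``.  The
    returned lists are disjoint and ordered as in the table.
    """
    df = table.df
    sig = (df["q_value"] < q_max) & df["q_value"].notna()
    up = df.index[sig & (df["neg_ddcq"] > ddcq_min)]
    down = df.index[sig & (df["neg_ddcq"] < -ddcq_min)]
    return (MirnaList("up", tuple(up)), MirnaList("down", tuple(down)))


def write_diff_table(table: DiffExpTable, path: str | Path) -> None:
    table.df.to_csv(path)


def read_diff_table(path: str | Path, **meta) -> DiffExpTable:
    df = pd.read_csv(path, index_col="mirna_id")
    missing = [c for c in _DIFF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing differential columns {missing}")
    return DiffExpTable(df[_DIFF_COLUMNS], **meta)
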