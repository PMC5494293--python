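"""Cross-cohort comparison of differential results and list algebra."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DiffExpTable
from .io import MirnaList, SampleSheet, canonical_mirna
from .normalization import NormalizedTable

__all__ = [
    "ConcordanceReport",
    "MatchedPairResult",
    "direction_concordance",
    "list_overlap",
    "matched_pair_diff",
]


@dataclass
class ConcordanceReport:
    """Direction agreement and rank correlation between two contrasts.

    ``per_mirna`` is indexed by panel miRNA with the paired ``neg_ddcq``
    effects, per-table directions and an ``agree`` flag (equal *nonzero*
    signs; a zero effect counts as disagreement with any nonzero sign).
    ``spearman_rho`` uses average ranks and covers miRNAs with effect
    estimates in both tables.
    """

    per_mirna: pd.DataFrame
    n_agree: int
    n_compared: int
    non_comparable: tuple[str, ...]
    spearman_rho: float

    @property
    def agreement_fraction(self) -> float:
        return self.n_agree / self.n_compared if self.n_compared else np.nan


def _sign(x: float) -> int:
    if np.isnan(x) or x == 0:
        return 0
    return 1 if x > 0 else -1


def direction_concordance(
    t1: DiffExpTable, t2: DiffExpTable, panel: MirnaList
) -> ConcordanceReport:
    """Compare up/down direction of panel miRNAs between two contrasts.

    Panel miRNAs absent from either table (or without an effect
    estimate) are listed as non-comparable and excluded from the
    agreement denominator and the correlation.
    """
    rows = []
    non_comparable = []
    for m in panel:
        in1, in2 = m in t1.df.index, m in t2.df.index
        e1 = t1.df.at[m, "neg_ddcq"] if in1 else np.nan
        e2 = t2.df.at[m, "neg_ddcq"] if in2 else np.nan
        if np.isnan(e1) or np.isnan(e2):
            non_comparable.append(m)
            continue
        s1, s2 = _sign(e1), _sign(e2)
        rows.append(
            {
                "mirna_id": m,
                "neg_ddcq_1": float(e1),
                "neg_ddcq_2": float(e2),
                "direction_1": {1: "up", -1: "down", 0: "none"}[s1],
                "direction_2": {1: "up", -1: "down", 0: "none"}[s2],
                "agree": s1 == s2 and s1 != 0,
            }
        )
    per = pd.DataFrame(rows).set_index("mirna_id") if rows else pd.DataFrame(
        columns=["neg_ddcq_1", "neg_ddcq_2", "direction_1", "direction_2", "agree"]
    )
    if len(per) >= 2 and per["neg_ddcq_1"].nunique() > 1 and per["neg_ddcq_2"].nunique() > 1:
        rho = float(stats.spearmanr(per["neg_ddcq_1"], per["neg_ddcq_2"]).statistic)
    else:
        rho = np.nan  # undefined for constant input or fewer than 2 pairs
    return ConcordanceReport(
        per_mirna=per,
        n_agree=int(per["agree"].sum()) if len(per) else 0,
        n_compared=len(per),
        non_comparable=tuple(non_comparable),
        spearman_rho=rho,
    )


def list_overlap(lists: Mapping[str, MirnaList]) -> pd.DataFrame:
    """Full Venn partition of two or more named miRNA lists.

    Returns one row per non-empty membership pattern with the pattern
    flags, region size and members (canonical exact-name matching).
    Region sizes sum to the size of the union.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    names = list(lists)
    sets = {n: set(lists[n].members) for n in names}
    rows = []
    for pattern in product([True, False], repeat=len(names)):
        if not any(pattern):
            continue
        inside = [n for n, flag in zip(names, pattern) if flag]
        outside = [n for n, flag in zip(names, pattern) if not flag]
        region = set.intersection(*(sets[n] for n in inside))
        for n in outside:
            region -= sets[n]
        rows.append(
            {
                **{f"in_{n}": flag for n, flag in zip(names, pattern)},
                "size": len(region),
                "members": ";".join(sorted(region)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MatchedPairResult:
    """Per-pair single-subject effects on a miRNA panel.

    ``effects`` is indexed by panel miRNA with one column per pair
    holding ``delta_cq(healthy) - delta_cq(periodontitis)`` — the
    single-pair analogue of ``neg_ddcq`` (positive = up in
    periodontitis).  ``summary`` adds per-miRNA sign counts and a
    ``consistent`` flag (all comparable pairs share one nonzero sign).
    """

    effects: pd.DataFrame
    summary: pd.DataFrame


def matched_pair_diff(
    norm: NormalizedTable,
    sheet: SampleSheet,
    pairs: Sequence[tuple[str, str]],
    panel: MirnaList,
) -> MatchedPairResult:
    """Compare matched (healthy, periodontitis) subject pairs on a panel."""
    sub = sheet.restrict(norm.sample_ids)
    cols = {}
    for h_id, p_id in pairs:
        for sid in (h_id, p_id):
            if sid not in norm.delta_cq.columns:
                raise ValueError(f"pair member {sid!r} absent from normalized table")
        if sub.data.at[h_id, "group"] != "healthy":
            raise ValueError(f"{h_id!r} is not a healthy sample")
        if sub.data.at[p_id, "group"] != "periodontitis":
            raise ValueError(f"{p_id!r} is not a periodontitis sample")
        cols[f"{h_id}_vs_{p_id}"] = norm.delta_cq[h_id] - norm.delta_cq[p_id]
    members = [canonical_mirna(m) for m in panel if m in norm.delta_cq.index]
    eff = pd.DataFrame(cols).loc[members]
    eff.index.name = "mirna_id"

    signs = np.sign(eff.to_numpy())
    n_pos = (signs > 0).sum(axis=1)
    n_neg = (signs < 0).sum(axis=1)
    n_missing = np.isnan(eff.to_numpy()).sum(axis=1)
    comparable = eff.shape[1] - n_missing
    consistent = ((n_pos == comparable) | (n_neg == comparable)) & (comparable > 0)
    summary = pd.DataFrame(
        {
            "n_up": n_pos,
            "n_down": n_neg,
            "n_non_comparable": n_missing,
            "consistent": consistent,
        },
        index=eff.index,
    )
    return MatchedPairResult(effects=eff, summary=summary)
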