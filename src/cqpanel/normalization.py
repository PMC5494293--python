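"""Cq-to-delta-Cq normalization and stability-based reference selection.

Two normalization schemes are provided:

* **global mean** — subtract each sample's mean detected Cq from every
  Cq of that sample (dense-panel discovery stage);
* **multi reference** — subtract each sample's mean Cq over a fixed set
  of reference probes, so that the per-sample reference average is
  identical (zero) across samples (targeted validation stage).

Reference probes are chosen by a geNorm-style pairwise-variation scheme:
a candidate's stability value M is the mean, over the other remaining
candidates, of the standard deviation across samples of the pairwise Cq
difference; the least stable candidate (largest M) is removed
iteratively until ``k`` remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CqTable, MirnaList, canonical_mirna

__all__ = [
    "NormalizedTable",
    "StabilityRanking",
    "global_mean_normalize",
    "multi_reference_normalize",
    "rank_stability",
    "fully_detected_mirnas",
]


@dataclass
class NormalizedTable:
    """Delta-Cq matrix plus a record of how it was produced.

    ``delta_cq`` has the same shape and labels as the source Cq matrix;
    undetected cells stay missing.  ``reference_set`` is empty for
    global-mean normalization.
    """

    delta_cq: pd.DataFrame
    method: str
    reference_set: MirnaList = field(default_factory=lambda: MirnaList("none", ()))

    def __post_init__(self) -> None:
        if self.method not in ("global_mean", "multi_reference"):
            raise ValueError(f"unknown normalization method {self.method!r}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.delta_cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.delta_cq.columns)


def global_mean_normalize(table: CqTable, *, common_only: bool = False) -> NormalizedTable:
    """Subtract each sample's average detected Cq from its Cq values.

    Parameters
    ----------
    table
        Raw Cq matrix.
    common_only
        If True, the per-sample average is taken over the miRNAs detected
        in *every* sample rather than over each sample's own detected set.

    Raises
    ------
    ValueError
        If any sample has no detected miRNA (the sample is named), or —
        with ``common_only`` — no miRNA is detected in all samples.
    """
    cq = table.cq
    if common_only:
        common = cq.index[cq.notna().all(axis=1)]
        if len(common) == 0:
            raise ValueError("common_only: no miRNA detected in every sample")
        means = cq.loc[common].mean(axis=0)
    else:
        n_det = cq.notna().sum(axis=0)
        empty = list(n_det.index[n_det == 0])
        if empty:
            raise ValueError(f"sample(s) with zero detected miRNAs: {empty}")
        means = cq.mean(axis=0)
    return NormalizedTable(cq.sub(means, axis=1), method="global_mean")


def multi_reference_normalize(table: CqTable, references: MirnaList) -> NormalizedTable:
    """Subtract the per-sample mean Cq of the reference probes.

    Every sample must detect every reference probe; by construction the
    per-sample mean delta-Cq over the references is zero.
    """
    if len(references) == 0:
        raise ValueError("empty reference set")
    missing = [m for m in references if m not in table.cq.index]
    if missing:
        raise ValueError(f"reference probe(s) absent from table: {missing}")
    ref_cq = table.cq.loc[list(references)]
    undet = ref_cq.isna()
    if undet.to_numpy().any():
        cells = [
            f"{probe}/{sample}"
            for probe, row in undet.iterrows()
            for sample, miss in row.items()
            if miss
        ]
        raise ValueError(f"reference probe undetected in sample(s): {cells}")
    r = ref_cq.mean(axis=0)
    return NormalizedTable(
        table.cq.sub(r, axis=1), method="multi_reference", reference_set=references
    )


def fully_detected_mirnas(table: CqTable) -> MirnaList:
    """miRNAs detected in 100% of samples (default stability candidates)."""
    ids = table.cq.index[table.cq.notna().all(axis=1)]
    return MirnaList("fully_detected", tuple(ids))


@dataclass
class StabilityRanking:
    """Result of the iterative pairwise-stability reference search.

    ``m_value`` holds the M value of every candidate computed on the full
    candidate set (before any exclusion); ``exclusion_order`` records the
    removed candidates with the M value they had at removal time, in
    removal order.
    """

    candidate_ids: tuple[str, ...]
    m_value: pd.Series
    exclusion_order: tuple[tuple[str, float], ...]
    selected_references: MirnaList


def _pairwise_sd(x: np.ndarray) -> np.ndarray:
    """SD (n-1 denominator) across samples of all pairwise row differences."""
    diff = x[:, None, :] - x[None, :, :]
    return diff.std(axis=2, ddof=1)


def rank_stability(
    table: CqTable, candidates: MirnaList | None = None, k: int = 5
) -> StabilityRanking:
    """Rank candidate reference probes by pairwise stability and select ``k``.

    At each step the stability value of candidate *j* among the remaining
    set R is ``M(j) = mean over j' in R, j' != j, of SD_samples(Cq_j -
    Cq_j')``; the candidate with the largest M is removed (ties broken by
    removing the lexicographically last name) until ``k`` remain.  The
    selected references are reported in lexicographic order.

    Candidates not detected in every sample are excluded up front rather
    than imputed.

    Notes
    -----
    Pairwise SDs are unchanged by removing a candidate, so the pairwise
    SD matrix is computed once and M values are formed by averaging over
    the remaining set — arithmetically identical to recomputing from
    scratch at every step.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if table.n_samples < 3:
        raise ValueError("stability ranking requires at least 3 samples")
    if candidates is None:
        candidates = fully_detected_mirnas(table)
    wanted = [canonical_mirna(m) for m in candidates]
    absent = [m for m in wanted if m not in table.cq.index]
    if absent:
        raise ValueError(f"candidate(s) absent from table: {absent}")
    full = table.cq.loc[wanted].notna().all(axis=1)
    usable = [m for m in wanted if full[m]]
    if len(usable) < k:
        raise ValueError(
            f"only {len(usable)} candidates detected in all samples; need >= {k}"
        )

    x = table.cq.loc[usable].to_numpy()
    sd = _pairwise_sd(x)  # symmetric, zero diagonal

    n = len(usable)
    remaining = list(range(n))
    m_initial = pd.Series(
        sd.sum(axis=1) / (n - 1), index=pd.Index(usable, name="mirna_id"), name="m_value"
    )

    exclusions: list[tuple[str, float]] = []
    while len(remaining) > k:
        idx = np.asarray(remaining)
        m_now = sd[np.ix_(idx, idx)].sum(axis=1) / (len(remaining) - 1)
        worst_m = m_now.max()
        # ties: remove the lexicographically last candidate name
        worst = max(usable[i] for i, m in zip(remaining, m_now) if m == worst_m)
        wi = usable.index(worst)
        exclusions.append((worst, float(worst_m)))
        remaining.remove(wi)

    selected = MirnaList("selected_references", tuple(sorted(usable[i] for i in remaining)))
    return StabilityRanking(
        candidate_ids=tuple(usable),
        m_value=m_initial,
        exclusion_order=tuple(exclusions),
        selected_references=selected,
    )
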