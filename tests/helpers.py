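"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each quantity from its plain definition
(python loops, no shared code with the package) so that implementation
and oracle can only agree if both match the definition.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def sd_oracle(values) -> float:
    """Sample standard deviation (n-1 denominator), from the definition."""
    vals = list(values)
    m = sum(vals) / len(vals)
    return math.sqrt(sum((v - m) ** 2 for v in vals) / (len(vals) - 1))


def genorm_brute_force(cq: dict[str, list[float]], k: int):
    """Iterative stability exclusion, recomputing every M from scratch.

    ``cq`` maps candidate name -> Cq values across samples.  Returns
    (selected set sorted, exclusion order list of (name, M)).  Ties at
    the argmax are broken by removing the lexicographically last name —
    the same convention the implementation documents.
    """
    remaining = sorted(cq)
    exclusions = []
    while len(remaining) > k:
        m_values = {}
        for j in remaining:
            sds = []
            for j2 in remaining:
                if j2 == j:
                    continue
                diffs = [a - b for a, b in zip(cq[j], cq[j2])]
                sds.append(sd_oracle(diffs))
            m_values[j] = sum(sds) / len(sds)
        worst_m = max(m_values.values())
        worst = max(name for name, m in m_values.items() if m == worst_m)
        exclusions.append((worst, worst_m))
        remaining.remove(worst)
    return sorted(remaining), exclusions


def bh_brute_force(p_values):
    """Step-up BH from the definition: q(i) = min over p(j) >= p(i) of m*p(j)/rank(j)."""
    pv = [p for p in p_values if not math.isnan(p)]
    m = len(pv)
    ranked = sorted(pv)

    def rank(p):  # largest rank among tied values
        return max(i + 1 for i, v in enumerate(ranked) if v == p)

    out = []
    for p in p_values:
        if math.isnan(p):
            out.append(float("nan"))
            continue
        q = min(m * pj / rank(pj) for pj in pv if pj >= p)
        out.append(min(q, 1.0))
    return out


def spearman_brute_force(x, y) -> float:
    """Rank (average ties) then Pearson, from the definitions."""

    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for idx in order[i : j + 1]:
                ranks[idx] = avg
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def student_t_brute_force(a, b):
    """Pooled-variance two-sample t statistic from the closed form."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((v - ma) ** 2 for v in a) / (na - 1)
    vb = sum((v - mb) ** 2 for v in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))


def random_cq_frame(rng, n_mirna=12, n_samples=5, missing_frac=0.0) -> pd.DataFrame:
    """Random detected-range Cq matrix with optional missing cells."""
    vals = rng.uniform(20, 35, size=(n_mirna, n_samples))
    if missing_frac > 0:
        mask = rng.random(vals.shape) < missing_frac
        vals = np.where(mask, np.nan, vals)
    return pd.DataFrame(
        vals,
        index=[f"hsa-mir-t-{i}" for i in range(n_mirna)],
        columns=[f"S{j}" for j in range(n_samples)],
    )
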