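"""Seeded generation of synthetic Cq panels with known ground truth.

The generative model on the Cq scale is::

    Cq(i, s) = B_i + o_s + beta_i * [s in periodontitis] + eps(i, s)

with per-miRNA baselines ``B_i``, per-sample loading offsets
``o_s ~ N(0, sample_offset_sd^2)``, additive group effects ``beta_i``
(negative for spiked-up miRNAs — lower Cq means higher expression —
positive for spiked-down, zero otherwise) and Gaussian replicate noise.
Designed reference probes carry zero effect and reduced noise.  Values
at or above ``censor_at`` are right-censored: marked undetected, never
truncated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import CqTable, MirnaList, SampleSheet

__all__ = ["SimConfig", "SimTruth", "generate_cq_dataset", "score_recovery"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic Cq panel generator."""

    n_mirna: int = 200
    n_healthy: int = 6
    n_perio: int = 6
    baseline_range: tuple[float, float] = (20.0, 37.0)
    ref_baseline_range: tuple[float, float] = (24.0, 30.0)
    sample_offset_sd: float = 1.0
    noise_sd: float = 0.5
    n_up: int = 10
    n_down: int = 10
    effect_cycles: float = 2.0
    effect_range: tuple[float, float] | None = None
    n_refs: int = 5
    ref_noise_sd: float = 0.1
    censor_at: float = 40.0
    seed: int = 0
    set_id: str = "set1"

    def __post_init__(self) -> None:
        if self.n_up + self.n_down + self.n_refs > self.n_mirna:
            raise ValueError("n_up + n_down + n_refs exceeds n_mirna")
        if min(self.sample_offset_sd, self.noise_sd, self.ref_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.effect_cycles < 0:
            raise ValueError("effect_cycles must be non-negative")
        if self.n_healthy < 1 or self.n_perio < 1:
            raise ValueError("each group needs at least one sample")
        if self.effect_range is not None and self.effect_range[0] > self.effect_range[1]:
            raise ValueError("effect_range must be (low, high)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        kwargs = dict(d)
        for key in ("baseline_range", "ref_baseline_range", "effect_range"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SimTruth:
    """Ground truth behind one generated dataset."""

    spiked_up: MirnaList
    spiked_down: MirnaList
    designed_refs: MirnaList
    baselines: pd.Series
    effects: pd.Series
    offsets: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "spiked_up": list(self.spiked_up),
            "spiked_down": list(self.spiked_down),
            "designed_refs": list(self.designed_refs),
            "baselines": self.baselines.to_dict(),
            "effects": self.effects.to_dict(),
            "offsets": self.offsets.to_dict(),
        }


def _mirna_names(config: SimConfig) -> tuple[list[str], list[str], list[str], list[str]]:
    wr = max(2, len(str(config.n_refs)))
    ws = max(3, len(str(max(config.n_up, config.n_down, 1))))
    wn = max(4, len(str(config.n_mirna)))
    refs = [f"hsa-mir-ref-{i + 1:0{wr}d}" for i in range(config.n_refs)]
    up = [f"hsa-mir-up-{i + 1:0{ws}d}" for i in range(config.n_up)]
    down = [f"hsa-mir-dn-{i + 1:0{ws}d}" for i in range(config.n_down)]
    n_null = config.n_mirna - config.n_refs - config.n_up - config.n_down
    null = [f"hsa-mir-null-{i + 1:0{wn}d}" for i in range(n_null)]
    return refs, up, down, null


def generate_cq_dataset(
    config: SimConfig,
    *,
    truth: SimTruth | None = None,
    seed: int | None = None,
) -> tuple[CqTable, SampleSheet, SimTruth]:
    """Draw one synthetic Cq dataset; reproducible for a fixed seed.

    Pass the ``truth`` of a previous call to reuse its baselines, spike
    assignments and effect sizes while drawing fresh samples (offsets
    and noise) — the way an independent validation cohort re-measures
    the same underlying biology.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    refs, up, down, null = _mirna_names(config)
    mirnas = refs + up + down + null

    if truth is None:
        baselines = pd.Series(
            np.concatenate(
                [
                    rng.uniform(*config.ref_baseline_range, size=config.n_refs),
                    rng.uniform(*config.baseline_range, size=len(mirnas) - config.n_refs),
                ]
            ),
            index=mirnas,
            name="baseline",
        )
        if config.effect_range is None:
            mag_up = np.full(config.n_up, config.effect_cycles)
            mag_down = np.full(config.n_down, config.effect_cycles)
        else:
            mag_up = rng.uniform(*config.effect_range, size=config.n_up)
            mag_down = rng.uniform(*config.effect_range, size=config.n_down)
        effects = pd.Series(0.0, index=mirnas, name="effect")
        effects[up] = -mag_up  # lower Cq in periodontitis = up-regulated
        effects[down] = +mag_down
    else:
        if list(truth.baselines.index) != mirnas:
            raise ValueError("truth does not match this configuration's panel")
        baselines = truth.baselines.copy()
        effects = truth.effects.copy()

    h_ids = [f"H{i + 1}" for i in range(config.n_healthy)]
    p_ids = [f"P{i + 1}" for i in range(config.n_perio)]
    samples = h_ids + p_ids
    is_perio = np.array([0.0] * config.n_healthy + [1.0] * config.n_perio)

    offsets = pd.Series(
        rng.normal(0.0, config.sample_offset_sd, size=len(samples)),
        index=samples,
        name="offset",
    )
    noise_sd = np.where(
        np.isin(mirnas, refs), config.ref_noise_sd, config.noise_sd
    )
    eps = rng.normal(0.0, 1.0, size=(len(mirnas), len(samples))) * noise_sd[:, None]

    cq = (
        baselines.to_numpy()[:, None]
        + offsets.to_numpy()[None, :]
        + effects.to_numpy()[:, None] * is_perio[None, :]
        + eps
    )
    cq = np.where(cq >= config.censor_at, np.nan, cq)

    table = CqTable(
        pd.DataFrame(cq, index=mirnas, columns=samples),
        panel_id=f"simulated-{config.set_id}",
        censor_at=config.censor_at,
    )
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": ["healthy"] * config.n_healthy
                + ["periodontitis"] * config.n_perio,
                "set_id": config.set_id,
                "age": np.concatenate(
                    [
                        rng.integers(25, 46, size=config.n_healthy),
                        rng.integers(35, 80, size=config.n_perio),
                    ]
                ),
                "gender": [("M", "F")[i % 2] for i in range(len(samples))],
                "diagnosis": ["H"] * config.n_healthy + ["CP"] * config.n_perio,
            }
        )
    )
    out_truth = SimTruth(
        spiked_up=MirnaList("spiked_up", tuple(up)),
        spiked_down=MirnaList("spiked_down", tuple(down)),
        designed_refs=MirnaList("designed_refs", tuple(refs)),
        baselines=baselines,
        effects=effects,
        offsets=offsets,
    )
    return table, sheet, out_truth


def _safe_ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def score_recovery(
    truth: SimTruth,
    up: MirnaList,
    down: MirnaList,
    refs: MirnaList | None = None,
) -> dict:
    """Confusion-style recovery metrics of pipeline output against truth.

    Precision is ``None`` (reported missing) when the corresponding call
    list is empty; ``refs_recovered`` counts designed references present
    in ``refs`` when given.
    """
    true_up, true_down = set(truth.spiked_up), set(truth.spiked_down)
    got_up, got_down = set(up.members), set(down.members)
    metrics = {
        "sensitivity_up": _safe_ratio(len(got_up & true_up), len(true_up)),
        "precision_up": _safe_ratio(len(got_up & true_up), len(got_up)),
        "sensitivity_down": _safe_ratio(len(got_down & true_down), len(true_down)),
        "precision_down": _safe_ratio(len(got_down & true_down), len(got_down)),
        "n_false_up": len(got_up - true_up),
        "n_false_down": len(got_down - true_down),
    }
    if refs is not None:
        metrics["refs_recovered"] = len(set(refs.members) & set(truth.designed_refs))
    return metrics
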