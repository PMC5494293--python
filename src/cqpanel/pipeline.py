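"""End-to-end two-stage workflow: discovery, validation, concordance.

The discovery stage normalizes a dense panel by the global mean and
screens for differential miRNAs; the validation stage normalizes a
targeted panel against reference probes (given or auto-selected by
stability ranking) and re-tests; the two contrasts are then compared for
direction concordance.  All numeric outputs are reproducible from the
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from . import __version__
from .differential import DiffExpTable, differential_table, select_candidates, write_diff_table
from .io import (
    CqTable,
    MirnaList,
    SampleSheet,
    file_sha256,
    filter_detected,
    read_cq_table,
    read_mirna_list,
    read_sample_sheet,
    write_cq_table,
    write_mirna_list,
    write_sample_sheet,
)
from .concordance import direction_concordance
from .normalization import (
    NormalizedTable,
    global_mean_normalize,
    multi_reference_normalize,
    rank_stability,
)
from .simulate import SimConfig, generate_cq_dataset

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "PcaResult",
    "ClusteringResult",
    "pca_samples",
    "hierarchical_heatmap",
    "run_pipeline",
]


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; the message names the stage."""


@dataclass
class PcaResult:
    """Sample coordinates and per-component variance fractions."""

    coordinates: pd.DataFrame  # samples x components
    variance_explained: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.variance_explained, dtype=float)
        if ((v < -1e-12) | (v > 1 + 1e-12)).any() or (np.diff(v) > 1e-12).any():
            raise ValueError("variance fractions must be in [0,1] and nonincreasing")
        self.variance_explained = v


def pca_samples(norm: NormalizedTable, n_components: int | None = None) -> PcaResult:
    """Principal components of samples on complete-case −ΔCq features.

    Only miRNAs detected in every sample enter (no imputation).  Samples
    are observations; features are mean-centered and decomposed by SVD.
    """
    complete = norm.delta_cq.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("fewer than 2 complete-case miRNAs; cannot run PCA")
    x = -complete.T.to_numpy()  # samples x features, expression scale
    x = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = (s**2).sum()
    frac = (s**2) / total if total > 0 else np.zeros_like(s)
    k = len(s) if n_components is None else min(n_components, len(s))
    coords = pd.DataFrame(
        (u * s)[:, :k],
        index=pd.Index(norm.sample_ids, name="sample_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PcaResult(coordinates=coords, variance_explained=frac[:k])


@dataclass
class ClusteringResult:
    """Two-way hierarchical clustering of a −ΔCq matrix for heatmaps."""

    matrix: pd.DataFrame  # -delta Cq, rows = miRNAs (NaN kept for display)
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    dropped_rows: tuple[str, ...]


def hierarchical_heatmap(
    norm: NormalizedTable,
    panel: MirnaList | None = None,
    *,
    metric: str = "euclidean",
    method: str = "average",
) -> ClusteringResult:
    """Cluster miRNAs and samples on −ΔCq values.

    Rows that are entirely missing are dropped (reported in
    ``dropped_rows``).  Remaining missing cells stay missing in the
    display matrix; for distance computation only, they are filled with
    the row mean.
    """
    import warnings

    mat = -norm.delta_cq
    if panel is not None:
        present = [m for m in panel if m in mat.index]
        mat = mat.loc[present]
    all_missing = mat.index[mat.isna().all(axis=1)]
    if len(all_missing):
        warnings.warn(
            f"dropping all-missing rows: {list(all_missing)}", UserWarning, stacklevel=2
        )
        mat = mat.drop(index=all_missing)
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns to cluster")

    filled = mat.apply(lambda row: row.fillna(row.mean()), axis=1)
    row_link = hierarchy.linkage(pdist(filled.to_numpy(), metric=metric), method=method)
    col_link = hierarchy.linkage(
        pdist(filled.to_numpy().T, metric=metric), method=method
    )
    row_order = tuple(mat.index[i] for i in hierarchy.leaves_list(row_link))
    col_order = tuple(mat.columns[i] for i in hierarchy.leaves_list(col_link))
    return ClusteringResult(
        matrix=mat,
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_link,
        col_linkage=col_link,
        dropped_rows=tuple(all_missing),
    )


@dataclass
class PipelineConfig:
    """Configuration of :func:`run_pipeline`.

    Either ``simulate`` (a :class:`SimConfig`-style mapping; a second
    validation set is drawn from the same truth) or explicit input paths
    must be provided.
    """

    outdir: str = "cqpanel_out"
    seed: int = 0
    discovery_cq: str | None = None
    validation_cq: str | None = None
    sample_sheet: str | None = None
    panel: str | None = None
    references: str | None = None
    n_references: int = 5
    q_max: float = 0.05
    ddcq_min: float = 1.0
    t_variant: str = "welch"
    censor_at: float = 40.0
    figures: bool = False
    simulate: Mapping | None = None

    def __post_init__(self) -> None:
        if self.q_max <= 0 or self.ddcq_min <= 0:
            raise ValueError("thresholds must be positive")
        if self.t_variant not in ("welch", "student"):
            raise ValueError(f"unknown t variant {self.t_variant!r}")
        if self.simulate is None and (self.discovery_cq is None or self.sample_sheet is None):
            raise ValueError("provide either simulate parameters or input paths")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the two-stage workflow and write the output bundle.

    Outputs (CSV tables, miRNA lists, JSON reports, optional figures)
    are only written once every stage has succeeded, so a failure leaves
    no partial bundle.  Returns the in-memory artifacts.
    """
    artifacts: dict = {}
    provenance: dict = {
        "tool": "cqpanel",
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "q_max": config.q_max,
            "ddcq_min": config.ddcq_min,
            "t_variant": config.t_variant,
            "censor_at": config.censor_at,
            "n_references": config.n_references,
        },
        "inputs": {},
        "stages": [],
    }

    @_stage("load")
    def load():
        if config.simulate is not None:
            sim = SimConfig.from_dict({**dict(config.simulate), "seed": config.seed})
            t1, sheet1, truth = generate_cq_dataset(sim)
            sim2 = dataclasses.replace(sim, set_id="set2")
            t2, sheet2, _ = generate_cq_dataset(sim2, truth=truth, seed=config.seed + 1)
            sheet2 = SampleSheet(
                sheet2.data.reset_index().assign(
                    sample_id=lambda d: "v_" + d["sample_id"]
                )
            )
            t2 = CqTable(
                t2.cq.set_axis(["v_" + s for s in t2.sample_ids], axis=1),
                panel_id=t2.panel_id,
                censor_at=t2.censor_at,
            )
            sheet = SampleSheet(pd.concat([sheet1.data, sheet2.data]).reset_index())
            artifacts["truth"] = truth
            provenance["inputs"]["simulate"] = dict(config.simulate)
            return t1, t2, sheet
        for key in ("discovery_cq", "validation_cq", "sample_sheet", "panel", "references"):
            p = getattr(config, key)
            if p is not None:
                provenance["inputs"][key] = {"path": str(p), "sha256": file_sha256(p)}
        t1 = read_cq_table(config.discovery_cq, censor_at=config.censor_at)
        t2 = (
            read_cq_table(config.validation_cq, censor_at=config.censor_at)
            if config.validation_cq
            else None
        )
        return t1, t2, read_sample_sheet(config.sample_sheet)

    table1, table2, sheet = load()

    @_stage("detection_filter")
    def detect():
        return filter_detected(table1, sheet)

    filt = detect()
    provenance["stages"].append(
        {"detection_filter": {"retained": filt.n_retained, "dropped": filt.n_dropped}}
    )

    @_stage("discovery_normalize")
    def norm_discovery():
        return global_mean_normalize(filt.table)

    norm1 = norm_discovery()

    @_stage("discovery_differential")
    def diff_discovery():
        return differential_table(
            norm1,
            sheet,
            t_variant=config.t_variant,
            q_max=config.q_max,
            ddcq_min=config.ddcq_min,
            set_id="set1",
        )

    diff1 = diff_discovery()
    up1, down1 = select_candidates(diff1, config.q_max, config.ddcq_min)
    artifacts.update(
        filter=filt, norm_discovery=norm1, diff_discovery=diff1, up=up1, down=down1
    )

    if config.panel is not None:
        panel = read_mirna_list(config.panel, name="panel")
    else:
        panel = MirnaList("panel", tuple(up1) + tuple(down1))
    artifacts["panel"] = panel

    @_stage("pca")
    def pca():
        return pca_samples(norm1)

    artifacts["pca_discovery"] = pca()

    if table2 is not None:
        @_stage("reference_selection")
        def select_refs():
            if config.references is not None:
                return read_mirna_list(config.references, name="references"), None
            ranking = rank_stability(table2, k=config.n_references)
            return ranking.selected_references, ranking

        references, ranking = select_refs()
        artifacts["references"] = references
        artifacts["stability_ranking"] = ranking

        @_stage("validation_normalize")
        def norm_validation():
            return multi_reference_normalize(table2, references)

        norm2 = norm_validation()

        @_stage("validation_differential")
        def diff_validation():
            return differential_table(
                norm2,
                sheet,
                t_variant=config.t_variant,
                q_max=config.q_max,
                ddcq_min=config.ddcq_min,
                set_id="set2",
            )

        diff2 = diff_validation()

        @_stage("concordance")
        def concord():
            return direction_concordance(diff1, diff2, panel)

        report = concord()
        artifacts.update(norm_validation=norm2, diff_validation=diff2, concordance=report)

    _write_bundle(config, artifacts, provenance)
    return artifacts


def _write_bundle(config: PipelineConfig, artifacts: dict, provenance: dict) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    filt = artifacts["filter"]
    write_cq_table(filt.table, out / "cq_filtered.csv")
    artifacts["norm_discovery"].delta_cq.to_csv(out / "normalized_discovery.csv")
    write_diff_table(artifacts["diff_discovery"], out / "diff_discovery.csv")
    write_mirna_list(artifacts["up"], out / "up_discovery.txt")
    write_mirna_list(artifacts["down"], out / "down_discovery.txt")
    write_mirna_list(artifacts["panel"], out / "panel.txt")

    pca_res = artifacts["pca_discovery"]
    pca_df = pca_res.coordinates.copy()
    pca_df.to_csv(out / "pca_discovery.csv")
    (out / "pca_variance_discovery.json").write_text(
        json.dumps({"variance_explained": pca_res.variance_explained.tolist()}, indent=2)
    )

    if "norm_validation" in artifacts:
        artifacts["norm_validation"].delta_cq.to_csv(out / "normalized_validation.csv")
        write_diff_table(artifacts["diff_validation"], out / "diff_validation.csv")
        write_mirna_list(artifacts["references"], out / "references.txt")
        rep = artifacts["concordance"]
        rep.per_mirna.to_csv(out / "concordance_per_mirna.csv")
        (out / "concordance.json").write_text(
            json.dumps(
                {
                    "n_agree": rep.n_agree,
                    "n_compared": rep.n_compared,
                    "agreement_fraction": rep.agreement_fraction,
                    "spearman_rho": rep.spearman_rho,
                    "non_comparable": list(rep.non_comparable),
                },
                indent=2,
            )
        )
    if "truth" in artifacts:
        (out / "truth.json").write_text(
            json.dumps(artifacts["truth"].to_json_dict(), indent=2)
        )
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))

    if config.figures:
        from . import plots

        plots.save_standard_figures(artifacts, out / "figures")
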