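"""Figure helpers (artifacts only; tests assert the underlying matrices)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .differential import DiffExpTable

__all__ = ["volcano_data", "plot_volcano", "plot_pca", "plot_heatmap", "save_standard_figures"]


def volcano_data(table: DiffExpTable) -> pd.DataFrame:
    """x/y coordinates of a volcano plot, regenerated from the table alone."""
    df = table.df
    return pd.DataFrame(
        {
            "neg_ddcq": df["neg_ddcq"],
            "neg_log10_q": -np.log10(df["q_value"]),
            "passes": df["passes"],
        },
        index=df.index,
    )


def plot_volcano(table: DiffExpTable, *, q_max=0.05, ddcq_min=1.0, ax=None):
    data = volcano_data(table).dropna()
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    hit = data["passes"].astype(bool)
    ax.scatter(data.loc[~hit, "neg_ddcq"], data.loc[~hit, "neg_log10_q"], s=8, c="grey")
    ax.scatter(data.loc[hit, "neg_ddcq"], data.loc[hit, "neg_log10_q"], s=10, c="red")
    ax.axhline(-np.log10(q_max), ls="--", lw=0.8, c="k")
    for x in (-ddcq_min, ddcq_min):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel(r"$-\Delta\Delta$Cq")
    ax.set_ylabel(r"$-\log_{10}$(q)")
    return ax


def plot_pca(pca_result, sheet=None, ax=None):
    coords = pca_result.coordinates
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    colors = None
    if sheet is not None:
        groups = sheet.data.loc[coords.index, "group"]
        colors = groups.map({"healthy": "tab:blue", "periodontitis": "tab:red"})
    ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], c=colors)
    for sid, row in coords.iterrows():
        ax.annotate(sid, (row.iloc[0], row.iloc[1]), fontsize=7)
    ve = pca_result.variance_explained
    ax.set_xlabel(f"PC1 ({ve[0] * 100:.1f}% variance)")
    if len(ve) > 1:
        ax.set_ylabel(f"PC2 ({ve[1] * 100:.1f}% variance)")
    return ax


def plot_heatmap(clustering, ax=None):
    mat = clustering.matrix.loc[list(clustering.row_order), list(clustering.col_order)]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(4, 0.15 * mat.shape[0])))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=6)
    ax.figure.colorbar(im, ax=ax, label=r"$-\Delta$Cq")
    return ax


def save_standard_figures(artifacts: dict, outdir: str | Path) -> None:
    """Write volcano/PCA figures for whatever artifacts are present."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if "diff_discovery" in artifacts:
        ax = plot_volcano(artifacts["diff_discovery"])
        ax.figure.savefig(outdir / "volcano_discovery.png", dpi=150)
        plt.close(ax.figure)
    if "diff_validation" in artifacts:
        ax = plot_volcano(artifacts["diff_validation"])
        ax.figure.savefig(outdir / "volcano_validation.png", dpi=150)
        plt.close(ax.figure)
    if "pca_discovery" in artifacts:
        ax = plot_pca(artifacts["pca_discovery"])
        ax.figure.savefig(outdir / "pca_discovery.png", dpi=150)
        plt.close(ax.figure)
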