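"""Tabular and graphical emission of DDM, overlay and interface results.

TSV/CSV tables are the contract surface (deterministic, diffable); figures
are best-effort matplotlib renderings — DDM heatmaps use a diverging
colormap centred at zero so contraction (negative) and expansion (positive)
read as opposite hues.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .ddm import BlockDDM, DDMatrix
from .interface import InterfaceReport

__all__ = [
    "write_ddm_tsv",
    "write_ddm_csv",
    "write_block_csv",
    "write_interface_tsv",
    "ddm_heatmap",
    "block_heatmap",
    "overlay_heatmap",
    "interface_bars",
]

_FLOAT_FMT = "%.6f"


def write_ddm_tsv(ddmatrix: DDMatrix, path: str | Path) -> None:
    """Long-format TSV: chain_i, res_i, chain_j, res_j, delta, masked."""
    df = ddmatrix.to_long_frame()
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_ddm_csv(ddmatrix: DDMatrix, path: str | Path) -> None:
    """Square-matrix CSV with residue labels."""
    ddmatrix.to_square_frame().to_csv(path, float_format=_FLOAT_FMT)


def write_block_csv(block: BlockDDM, path: str | Path) -> None:
    block.to_frame().to_csv(path, float_format=_FLOAT_FMT)


def write_interface_tsv(report: InterfaceReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _diverging(ax, values: np.ndarray, labels: list[str] | None, title: str):
    finite = values[np.isfinite(values)]
    vmax = float(np.abs(finite).max()) if finite.size else 1.0
    vmax = vmax or 1.0
    im = ax.imshow(values, cmap="PiYG_r", vmin=-vmax, vmax=vmax, origin="lower")
    ax.set_title(title)
    if labels is not None and len(labels) <= 40:
        ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
        ax.set_yticks(range(len(labels)), labels, fontsize=6)
    return im


def ddm_heatmap(ddmatrix: DDMatrix, path: str | Path, title: str = "DDM",
                apply_mask: bool = False) -> None:
    values = ddmatrix.values.copy()
    if apply_mask:
        values[ddmatrix.mask] = 0.0
    fig, ax = plt.subplots(figsize=(6, 5))
    im = _diverging(ax, values, None, title)
    fig.colorbar(im, ax=ax, label="Δ distance (Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def block_heatmap(block: BlockDDM, path: str | Path, title: str = "Block DDM") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = _diverging(ax, block.values, block.block_names, title)
    fig.colorbar(im, ax=ax, label="mean Δ distance (Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def overlay_heatmap(ddmatrix: DDMatrix, overlay_table: pd.DataFrame,
                    path: str | Path, title: str = "DDM + EC overlay") -> None:
    """DDM heatmap with EC pairs marked as dots at (i, j) and (j, i)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    im = _diverging(ax, ddmatrix.values, None, title)
    pos = {k.residue_number: idx for idx, k in enumerate(ddmatrix.keys)}
    if not overlay_table.empty:
        xs, ys = [], []
        for _, row in overlay_table.iterrows():
            i, j = pos.get(int(row["i"])), pos.get(int(row["j"]))
            if i is None or j is None:
                continue
            xs += [i, j]
            ys += [j, i]
        ax.scatter(xs, ys, s=4, c="black", marker=".")
    fig.colorbar(im, ax=ax, label="Δ distance (Å)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def interface_bars(report: InterfaceReport, path: str | Path,
                   title: str = "Interface areas") -> None:
    df = report.to_frame()
    if df.empty:
        return
    fig, ax = plt.subplots(figsize=(7, 4))
    pairs = df["selection_a"] + "|" + df["selection_b"]
    for state, grp in df.assign(pair=pairs).groupby("state"):
        ax.bar(grp["pair"], grp["interface_area"], alpha=0.6, label=f"state {state}")
    ax.axhline(report.affinity_threshold, ls="--", c="grey", lw=1,
               label="strong-affinity threshold")
    ax.set_ylabel("interface area (Å²)")
    ax.set_title(title)
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
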