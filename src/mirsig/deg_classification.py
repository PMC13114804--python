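"""Harmonized significance thresholding, volcano tables, top-N reporting.

A gene is called significant when its BH-adjusted p-value falls below
``fdr_max`` (strict inequality) and its |log2 fold-change| reaches
``abs_lfc_min`` (non-strict), the harmonized thresholds applied identically
to every cohort.  Low-signal cohorts, where almost nothing survives the FDR
ceiling, can still be reported through an FDR-rank fallback that labels the
top genes by significance ranking alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .toptable_io import DETable, FDR_FLOOR

logger = logging.getLogger(__name__)

UP, DOWN, NS = "up", "down", "ns"


@dataclass(frozen=True)
class ThresholdConfig:
    """Harmonized significance thresholds (FDR < 0.05, |log2FC| >= 1)."""

    fdr_max: float = 0.05
    abs_lfc_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ConfigError(f"fdr_max must be in (0,1], got {self.fdr_max}")
        if self.abs_lfc_min < 0:
            raise ConfigError(f"abs_lfc_min must be >= 0, got {self.abs_lfc_min}")


def classify_gene(
    log2fc: float, fdr: float, thresholds: ThresholdConfig = ThresholdConfig()
) -> str:
    """Classify one gene as 'up', 'down' or 'ns' under the thresholds."""
    if fdr < thresholds.fdr_max:
        if log2fc >= thresholds.abs_lfc_min:
            return UP
        if log2fc <= -thresholds.abs_lfc_min:
            return DOWN
    return NS


def classify_table(
    table: DETable, thresholds: ThresholdConfig = ThresholdConfig()
) -> pd.Series:
    """Vectorized :func:`classify_gene` over a curated table."""
    df = table.df
    sig = df["fdr"] < thresholds.fdr_max
    out = pd.Series(NS, index=df.index, dtype=object)
    out[sig & (df["log2fc"] >= thresholds.abs_lfc_min)] = UP
    out[sig & (df["log2fc"] <= -thresholds.abs_lfc_min)] = DOWN
    return out


@dataclass
class DirectionalGeneSet:
    """Direction-annotated significant gene set for one cohort."""

    label: str
    direction_of: dict[str, str] = field(default_factory=dict)
    stats_of: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    @property
    def up(self) -> set[str]:
        return {s for s, d in self.direction_of.items() if d == UP}

    @property
    def down(self) -> set[str]:
        return {s for s, d in self.direction_of.items() if d == DOWN}

    @property
    def counts(self) -> tuple[int, int, int]:
        """(n_up, n_down, total)."""
        n_up, n_down = len(self.up), len(self.down)
        return n_up, n_down, n_up + n_down


def significant_sets(
    table: DETable, thresholds: ThresholdConfig = ThresholdConfig()
) -> DirectionalGeneSet:
    """All significant genes of one cohort with direction and statistics."""
    cls = classify_table(table, thresholds)
    result = DirectionalGeneSet(label=table.dataset_id)
    sig = table.df.loc[cls != NS]
    for row, direction in zip(sig.itertuples(index=False), cls[cls != NS]):
        result.direction_of[row.symbol] = direction
        result.stats_of[row.symbol] = {
            table.dataset_id: (float(row.log2fc), float(row.fdr))
        }
    n_up, n_down, total = result.counts
    logger.info("%s: %d up, %d down, %d significant total",
                table.dataset_id, n_up, n_down, total)
    return result


def _rank(df: pd.DataFrame) -> pd.DataFrame:
    # deterministic chain: FDR asc, |log2fc| desc, symbol asc
    return (
        df.assign(_abs=df["log2fc"].abs())
        .sort_values(["fdr", "_abs", "symbol"], ascending=[True, False, True],
                     kind="stable")
        .drop(columns="_abs")
        .reset_index(drop=True)
    )


def top_ranked(
    table: DETable,
    n_per_direction: int = 10,
    mode: str = "significant_only",
    thresholds: ThresholdConfig = ThresholdConfig(),
) -> dict[str, pd.DataFrame]:
    """Top-N genes per direction, ranked by ascending FDR.

    ``significant_only`` restricts to genes passing the thresholds;
    ``fdr_rank_fallback`` takes direction from the sign of log2fc regardless
    of significance, the labeling rule used for low-signal cohorts.  Returns
    ``{"up": ..., "down": ..., "combined": ...}``.
    """
    if n_per_direction < 1:
        raise ConfigError("n_per_direction must be >= 1")
    if mode not in {"significant_only", "fdr_rank_fallback"}:
        raise ConfigError(f"unknown mode {mode!r}")
    df = table.df
    if mode == "significant_only":
        cls = classify_table(table, thresholds)
        up_pool = df.loc[cls == UP]
        down_pool = df.loc[cls == DOWN]
    else:
        up_pool = df.loc[df["log2fc"] > 0]
        down_pool = df.loc[df["log2fc"] < 0]

    up = _rank(up_pool).head(n_per_direction)
    down = _rank(down_pool).head(n_per_direction)
    for name, block, pool in (("up", up, up_pool), ("down", down, down_pool)):
        if len(block) < n_per_direction:
            warnings.warn(
                f"{table.dataset_id}: only {len(block)} {name} gene(s) "
                f"available for top-{n_per_direction} report", stacklevel=2
            )
    combined = pd.concat(
        [up.assign(direction=UP), down.assign(direction=DOWN)], ignore_index=True
    )
    return {"up": up, "down": down, "combined": combined}


def volcano_table(
    table: DETable, thresholds: ThresholdConfig = ThresholdConfig()
) -> pd.DataFrame:
    """Plot-ready rows: x = log2fc, y = -log10(FDR), class per gene.

    Threshold reference lines are recorded in ``DataFrame.attrs``.
    """
    df = table.df
    out = pd.DataFrame(
        {
            "symbol": df["symbol"],
            "x": df["log2fc"],
            "y": -np.log10(df["fdr"].clip(lower=FDR_FLOOR)),
            "class": classify_table(table, thresholds),
        }
    )
    out.attrs["vlines"] = (-thresholds.abs_lfc_min, thresholds.abs_lfc_min)
    out.attrs["hline"] = -np.log10(thresholds.fdr_max)
    out.attrs["dataset_id"] = table.dataset_id
    return out


def plot_volcano(vdf: pd.DataFrame, path: str | Path | None = None):
    """Render a volcano PNG from a :func:`volcano_table` frame (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {UP: "tab:orange", DOWN: "tab:green", NS: "0.7"}
    for cls, sub in vdf.groupby("class"):
        ax.scatter(sub["x"], sub["y"], s=6, c=colors.get(cls, "0.7"), label=cls)
    for xv in vdf.attrs.get("vlines", ()):
        ax.axvline(xv, ls="--", lw=0.8, c="k")
    if "hline" in vdf.attrs:
        ax.axhline(vdf.attrs["hline"], ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold-change")
    ax.set_ylabel("-log10(FDR)")
    ax.set_title(vdf.attrs.get("dataset_id", ""))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return fig


def write_top_gene_workbook(
    blocks: Mapping[str, pd.DataFrame], path: str | Path
) -> Path:
    """Export the top-gene report as XLSX: up / down / combined sheets."""
    path = Path(path)
    with pd.ExcelWriter(path, engine="openpyxl") as xl:
        for sheet in ("up", "down", "combined"):
            blocks[sheet].to_excel(xl, sheet_name=sheet, index=False)
    return path
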