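"""Minimal plots: per-chromosome RRD scatter and a fitted survival curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .dosage import RRDTable
from .survival import SurvivalCurveFit, survival_probability

__all__ = ["plot_rrd", "plot_survival"]


def plot_rrd(rrd: RRDTable, path: str | Path, chroms: list[str] | None = None) -> None:
    """One scatter panel of RRD vs bin midpoint per chromosome."""
    frame = rrd.bins
    if chroms is None:
        chroms = list(dict.fromkeys(frame["chrom"]))
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(8, 1.8 * len(chroms)), squeeze=False, sharey=True
    )
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = frame[frame["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.scatter(mid, sub["rrd"], s=6)
        ax.axhline(1.0, color="gray", lw=0.5)
        ax.set_ylabel("RRD")
        ax.set_title(chrom, fontsize=8)
        ax.set_ylim(0, 1.6)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_survival(
    data: pd.DataFrame, fit: SurvivalCurveFit, path: str | Path
) -> None:
    """Observed survival fractions with the fitted multitarget curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    frac = data["n_survived"] / data["n_total"]
    ax.scatter(data["dose_gy"], frac, label="observed")
    grid = np.linspace(0, float(data["dose_gy"].max()) * 1.05, 200)
    ax.plot(grid, survival_probability(grid, fit.D0, fit.N),
            label=f"fit: D0={fit.D0:.1f} Gy, N={fit.N:.1f}")
    ax.axvline(fit.Dq, ls="--", color="gray", label=f"Dq={fit.Dq:.1f} Gy")
    ax.set_xlabel("dose (Gy)")
    ax.set_ylabel("survival fraction")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
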