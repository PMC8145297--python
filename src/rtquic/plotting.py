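"""Presentation-only curve plots.

Mirrors the study's figure style: one panel per sample, the mean of the
replicate wells at each dilution plotted against time, with the per-plate
positivity threshold drawn as a horizontal line.  Plots are never consumed
by the analysis — all calling operates on individual wells.
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import PlateRun

__all__ = ["plot_curves", "replicate_mean_traces"]


def replicate_mean_traces(plate: PlateRun) -> dict[tuple[str, int], np.ndarray]:
    """Arithmetic mean of the replicate traces per (sample, dilution)."""
    traces: dict[tuple[str, int], np.ndarray] = {}
    for key, well_ids in plate.iter_groups():
        stack = np.vstack([plate.wells[w].fluorescence for w in well_ids])
        traces[key] = stack.mean(axis=0)
    return traces


def plot_curves(
    plate: PlateRun,
    threshold: float,
    out_path: str | Path,
) -> Path:
    """Write a one-figure-per-plate panel grid of replicate-mean traces."""
    means = replicate_mean_traces(plate)
    samples = sorted({sid for sid, _ in means})
    n = max(len(samples), 1)
    ncols = min(3, n)
    nrows = math.ceil(n / ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.0 * ncols, 3.0 * nrows),
        sharex=True, sharey=True, squeeze=False,
    )
    times = plate.time_grid.times_h
    for i, sid in enumerate(samples):
        ax = axes[i // ncols][i % ncols]
        for (s, exponent), trace in sorted(means.items(), key=lambda kv: -kv[0][1]):
            if s != sid:
                continue
            ax.plot(times, trace, label=f"$10^{{{exponent}}}$")
        ax.axhline(threshold, color="0.4", linestyle="--", linewidth=1)
        ax.set_title(sid, fontsize=9)
        ax.legend(fontsize=6, frameon=False)
    for j in range(len(samples), nrows * ncols):
        axes[j // ncols][j % ncols].set_axis_off()
    for ax in axes[-1]:
        ax.set_xlabel("time (h)")
    for row in axes:
        row[0].set_ylabel("ThT fluorescence (RFU)")
    fig.suptitle(plate.plate_id)
    fig.tight_layout()
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
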