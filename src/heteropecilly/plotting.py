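"""Histogram plots comparing observed and null-replicate heteropecilly."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import PIPResult


def plot_fdp_histogram(real_fdps: Sequence[float],
                       sim_fdps: Sequence[float] | None = None,
                       path: str | Path = "fdp_hist.png") -> None:
    """Stacked FDP distributions: observed (blue) vs null replicates (purple)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, 1, 21)
    ax.hist(list(real_fdps), bins=bins, color="tab:blue", alpha=0.7,
            label="observed")
    if sim_fdps is not None and len(list(sim_fdps)):
        ax.hist(list(sim_fdps), bins=bins, color="purple", alpha=0.5,
                label="null replicates")
    ax.set_xlabel("FDP")
    ax.set_ylabel("clade pairs")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_pip_histogram(real: PIPResult, sim: PIPResult | None = None,
                       path: str | Path = "pip_hist.png",
                       max_neg_log: float = 30.0) -> None:
    """-ln(PIP_n) distributions; PIP = 0 sites get their own rightmost bar."""
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = np.linspace(0, max_neg_log, 31)

    def series(p: PIPResult) -> np.ndarray:
        vals = p.neg_log_pip[~p.zero_flag]
        return np.clip(vals, 0, max_neg_log)

    ax.hist(series(real), bins=bins, color="tab:blue", alpha=0.7,
            label="observed")
    if sim is not None:
        ax.hist(series(sim), bins=bins, color="purple", alpha=0.5,
                label="null replicates")
    n_zero = int(real.zero_flag.sum())
    ax.bar([max_neg_log + 2], [n_zero], width=1.5, color="tab:blue", alpha=0.7)
    ax.text(max_neg_log + 2, n_zero, "PIP=0", ha="center", va="bottom",
            fontsize=8)
    ax.set_xlabel("-ln(PIP_n)")
    ax.set_ylabel("sites")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
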