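"""Standard figures: tornado diagram, cost-effectiveness plane, CEAC."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .analysis import Ceac, TornadoEntry, WtpThresholds


def plot_tornado(entries: Iterable[TornadoEntry], base_icer: float,
                 path: str | Path) -> None:
    entries = [e for e in entries if not math.isnan(e.width)]
    entries = entries[::-1]  # widest on top
    fig, ax = plt.subplots(figsize=(7, max(2, 0.35 * len(entries))))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_low, e.icer_high))
        ax.barh(i, hi - lo, left=lo, color="#4878d0", height=0.6)
    ax.axvline(base_icer, color="k", lw=1)
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.name for e in entries])
    ax.set_xlabel("ICER (VND per QALY)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ce_plane(draws: pd.DataFrame, path: str | Path,
                  thresholds: WtpThresholds = WtpThresholds()) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(draws["dqaly"], draws["dcost"], s=4, alpha=0.3, color="#4878d0")
    lim = max(abs(draws["dqaly"]).max(), 1e-9)
    q = pd.Series([-lim, lim])
    ax.plot(q, thresholds.gdp1 * q, color="green", lw=1, label="1 GDP/QALY")
    ax.plot(q, thresholds.gdp3 * q, color="orange", lw=1, label="3 GDP/QALY")
    ax.axhline(0, color="k", lw=0.5)
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (VND)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(curve: Ceac, path: str | Path,
              thresholds: WtpThresholds = WtpThresholds()) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp / 1e6, curve.probability, color="#4878d0")
    ax.axvline(thresholds.gdp1 / 1e6, color="green", lw=1, label="1 GDP")
    ax.axvline(thresholds.gdp3 / 1e6, color="orange", lw=1, label="3 GDP")
    ax.set_xlabel("Willingness-to-pay (million VND per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
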