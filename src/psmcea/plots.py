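"""Matplotlib figures for the standard outputs: tornado, CEAC, scatter, KM overlay."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_tornado", "plot_ceac", "plot_scatter", "plot_km_overlay"]


def plot_tornado(entries, base_icer: float, path, top: int = 12) -> None:
    entries = list(entries)[:top][::-1]
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(entries) + 1.5))
    for i, e in enumerate(entries):
        lo, hi = sorted((e.icer_at_low, e.icer_at_high))
        ax.barh(i, hi - lo, left=lo, height=0.6, color="#4878d0")
    ax.axvline(base_icer, color="k", ls="--", lw=1, label="base-case ICER")
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels([e.param for e in entries], fontsize=8)
    ax.set_xlabel("ICER (USD/QALY)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(sample_set, path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for strategy in sample_set.strategies:
        ax.plot(sample_set.ceac["wtp"] / 1000.0, sample_set.ceac[strategy],
                label=strategy)
    ax.set_xlabel("willingness to pay (thousand USD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter(sample_set, path, wtp: float = 150_000) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(sample_set.draws["incr_qalys"], sample_set.draws["incr_cost"] / 1e6,
               s=8, alpha=0.5)
    q = np.linspace(*ax.get_xlim(), 10)
    ax.plot(q, wtp * q / 1e6, "k--", lw=1, label=f"WTP {wtp:,.0f}/QALY")
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (million USD)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_km_overlay(curve, fits, path, horizon: float | None = None) -> None:
    """Digitized KM step curve with the fitted parametric curves on top."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.step(curve.times, curve.survival, where="post", color="k", lw=1.5,
            label="digitized KM")
    tmax = horizon or float(curve.times[-1])
    grid = np.linspace(0, tmax, 400)
    for fit in fits:
        ax.plot(grid, fit.dist.sf(grid), lw=1,
                label=f"{fit.family} (AIC {fit.aic:.0f})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
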