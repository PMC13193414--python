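"""Diagnostic plots: scree/EVR, loss curves, calibration, attention."""

from __future__ import annotations

import numpy as np

from .eigen import EigenSpectrum


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def scree_plot(spectrum: EigenSpectrum, alpha: float | None = None, ax=None):
    """Eigenvalue bars with the cumulative explained-variance curve."""
    ax = _get_ax(ax)
    ks = np.arange(1, spectrum.d + 1)
    ax.bar(ks, spectrum.eigenvalues, color="tab:blue", alpha=0.7, label="eigenvalue")
    ax2 = ax.twinx()
    ax2.plot(ks, spectrum.evr, "r-o", ms=3, label="cumulative EVR")
    if alpha is not None:
        ax2.axhline(alpha, ls="--", color="grey")
    ax2.set_ylim(0, 1.02)
    ax.set_xlabel("component")
    ax.set_ylabel("eigenvalue")
    ax2.set_ylabel("cumulative EVR")
    return ax


def loss_curves(history, ax=None):
    """Per-epoch training and validation MSE."""
    ax = _get_ax(ax)
    ax.plot(history["epoch"], history["train_loss"], label="train")
    ax.plot(history["epoch"], history["val_loss"], label="validation")
    ax.set_xlabel("epoch")
    ax.set_ylabel("MSE")
    ax.legend()
    return ax


def calibration_curve(table, ax=None):
    """Observed vs expected interval coverage with the identity line."""
    ax = _get_ax(ax)
    ax.plot([0, 1], [0, 1], "k--", lw=1)
    ax.plot(table["expected_coverage"], table["observed_coverage"], "o-")
    ax.set_xlabel("expected coverage")
    ax.set_ylabel("observed coverage")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    return ax


def attention_heatmap(summary, ax=None):
    """Head-averaged temporal attention of the final block."""
    ax = _get_ax(ax)
    im = ax.imshow(summary.heatmap, cmap="viridis", aspect="auto")
    ax.set_xlabel("key (day in lookback)")
    ax.set_ylabel("query (day in lookback)")
    ax.figure.colorbar(im, ax=ax, label="attention weight")
    return ax
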