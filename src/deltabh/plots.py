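"""Diagnostic plots: parity, signed-error histogram, learning curve."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def parity_plot(reference: np.ndarray, predicted: np.ndarray, path: str | Path,
                label: str = "barrier height (kcal/mol)") -> Path:
    """Predicted vs reference scatter with the identity line."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lo = min(np.min(reference), np.min(predicted))
    hi = max(np.max(reference), np.max(predicted))
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.scatter(reference, predicted, s=12, alpha=0.6)
    ax.set_xlabel(f"reference {label}")
    ax.set_ylabel(f"predicted {label}")
    mae = float(np.abs(np.asarray(predicted) - np.asarray(reference)).mean())
    ax.set_title(f"MAE = {mae:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def error_histogram(errors: np.ndarray, path: str | Path, bins: int = 20) -> Path:
    """Histogram of signed prediction errors."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.hist(errors, bins=bins, edgecolor="black", alpha=0.8)
    ax.axvline(0.0, color="k", lw=1)
    ax.set_xlabel("signed error (kcal/mol)")
    ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def learning_curve_plot(table: pd.DataFrame, path: str | Path) -> Path:
    """MAE vs training-set size with one-sd error bars (log-x)."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.errorbar(table["n_train"], table["mae_mean"], yerr=table["mae_sd"],
                marker="o", capsize=3)
    ax.set_xscale("log")
    ax.set_xlabel("training reactions")
    ax.set_ylabel("test MAE (kcal/mol)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
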