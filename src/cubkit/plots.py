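"""Diagnostic plots: ENC-plot, PR2-plot, neutrality plot and CoA axes."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .selection_inference import CoAResult, RegressionResult, expected_enc

__all__ = ["enc_plot", "pr2_plot", "neutrality_plot", "coa_plot"]

_GC_COLORS = {"low": "tab:blue", "mid": "tab:red", "high": "tab:green"}


def _save(fig, path: str | Path) -> None:
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def enc_plot(gc3s, enc_obs, path: str | Path, title: str = "") -> None:
    """Per-gene ENC against GC3s with the mutation-only expected curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(gc3s, enc_obs, s=4, alpha=0.4, color="tab:blue")
    s = np.linspace(0.0, 1.0, 200)
    ax.plot(s, expected_enc(s), color="black", lw=1.2, label="expected")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 65)
    ax.set_title(title)
    ax.legend(frameon=False)
    _save(fig, path)


def pr2_plot(x, y, path: str | Path, title: str = "") -> None:
    """G3/(G3+C3) against A3/(A3+T3) with parity crosshairs at 0.5."""
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(x, y, s=4, alpha=0.4, color="tab:blue")
    ax.axhline(0.5, color="black", lw=0.8)
    ax.axvline(0.5, color="black", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    ax.set_title(title)
    _save(fig, path)


def neutrality_plot(
    gc3, gc12, fit: RegressionResult, path: str | Path, title: str = ""
) -> None:
    """GC12 against GC3 with the fitted regression line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(gc3, gc12, s=4, alpha=0.4, color="tab:blue")
    xs = np.array([np.nanmin(gc3), np.nanmax(gc3)])
    ax.plot(xs, fit.intercept + fit.slope * xs, color="black", lw=1.2,
            label=f"slope {fit.slope:.3f}, r {fit.pearson_r:.2f}")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.set_title(title)
    ax.legend(frameon=False)
    _save(fig, path)


def coa_plot(
    result: CoAResult, gc_labels: list[str] | None, path: str | Path,
    title: str = "",
) -> None:
    """Genes on CoA axes 1-2, coloured by GC class when labels are given."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    coords = result.row_coords
    if coords.shape[1] < 2:
        coords = coords.assign(axis2=0.0)
    pct = result.inertia_percent
    if gc_labels is None:
        ax.scatter(coords.iloc[:, 0], coords.iloc[:, 1], s=4, alpha=0.4)
    else:
        labels = pd.Series(gc_labels, index=coords.index)
        for cls, color in _GC_COLORS.items():
            sub = coords[labels == cls]
            if len(sub):
                ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=4, alpha=0.5,
                           color=color, label=cls)
        ax.legend(frameon=False, title="GC class")
    ax.set_xlabel(f"Axis 1 ({pct[0]:.2f}%)" if len(pct) else "Axis 1")
    ax.set_ylabel(f"Axis 2 ({pct[1]:.2f}%)" if len(pct) > 1 else "Axis 2")
    ax.set_title(title)
    _save(fig, path)
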