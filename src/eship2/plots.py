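"""Bland-Altman plots of device-minus-reference differences."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; plots are optional artifacts
import matplotlib.pyplot as plt

from .agreement import AgreementSummary

__all__ = ["bland_altman_plot"]

_UNITS = {"sbp": "mm Hg", "dbp": "mm Hg", "hr": "beats/min"}


def bland_altman_plot(
    summary: AgreementSummary,
    path: str | Path | None = None,
    ax: "plt.Axes | None" = None,
) -> "plt.Axes":
    """Scatter of signed differences against pair means with bias and limits of agreement."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if summary.points:
        xs, ys = zip(*summary.points)
        ax.scatter(xs, ys, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(summary.bias, color="tab:blue", lw=1.2, label=f"bias {summary.bias:.2f}")
    for y, label in ((summary.loa_lower, "lower LoA"), (summary.loa_upper, "upper LoA")):
        ax.axhline(y, color="tab:red", lw=1.0, ls="--", label=f"{label} {y:.2f}")
    unit = _UNITS.get(summary.quantity, "")
    ax.set_xlabel(f"mean of device and reference ({unit})")
    ax.set_ylabel(f"device - reference ({unit})")
    ax.set_title(f"Bland-Altman: {summary.quantity.upper()}")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
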