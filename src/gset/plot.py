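"""Spectrum plotting with called landmarks annotated."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .histio import KmerHistogram
from .peakcall import PeakCall

__all__ = ["plot_spectrum"]


def plot_spectrum(hist: KmerHistogram, call: PeakCall | None,
                  path: str | Path, log_y: bool = True) -> None:
    """Render the unique-k-mer spectrum; annotate L, V and M when supplied."""
    fig, ax = plt.subplots(figsize=(8, 5))
    ax.plot(hist.x, hist.y, drawstyle="steps-mid", lw=1.2, color="#1f77b4")
    if log_y:
        ax.set_yscale("log")
    if call is not None:
        if call.L > 0:
            ax.axvline(call.L, color="grey", ls="--", lw=1,
                       label=f"error cutoff L={call.L}")
        ax.plot(*call.valley, "v", color="#d62728", ms=9,
                label=f"valley V({call.xv}, {call.yv})")
        ax.plot(*call.peak, "^", color="#2ca02c", ms=9,
                label=f"peak M({call.xm}, {call.ym})")
        ax.legend(frameon=False)
    ax.set_xlabel("k-mer frequency x")
    ax.set_ylabel("distinct k-mers y")
    title = "unique k-mer spectrum"
    if hist.k is not None:
        title += f" (k={hist.k})"
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
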