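"""Calibration plots: binned predicted probability vs observed frequency."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_calibration(eval_reports: dict[str, dict], path: str | Path) -> None:
    """One calibration curve per model family, with the diagonal of
    perfect calibration; writes PNG or SVG by file extension."""
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1, label="perfect")
    for family, rep in eval_reports.items():
        pts = [(b["mean_predicted"], b["observed_frequency"])
               for b in rep["calibration"] if b["n"] > 0]
        if not pts:
            continue
        xs, ys = zip(*pts)
        ax.plot(xs, ys, marker="o", ms=4, label=family)
    ax.set_xlabel("mean predicted probability")
    ax.set_ylabel("observed frequency")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    ax.set_title("Calibration: never-agreement prediction")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
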