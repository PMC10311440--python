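"""Figure helpers: VPC bands and forest-style comparison plots (SVG/PNG)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .compare import ComparisonResult
from .inference import VPCResult

__all__ = ["plot_vpc", "plot_forest"]


def plot_vpc(res: VPCResult, path: str | Path, title: str = "") -> None:
    """Shaded 95% prediction band with the observed curve overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(res.grid, res.lo, res.hi, alpha=0.3, label="95% PI")
    ax.plot(res.grid, res.mid, lw=1, label="predicted median")
    if res.kind == "os":
        ax.step(res.grid, res.observed, where="post", color="k", label="observed KM")
        ax.set_xlabel("time (months)")
        ax.set_ylabel("survival probability")
    else:
        ax.plot(res.grid, res.observed, "ko", label="observed rate")
        ax.set_xlabel("AUCu (ng·h/L)")
        ax.set_ylabel("response rate")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_forest(results: dict[str, ComparisonResult], path: str | Path) -> None:
    """Forest-style plot of head-to-head effects with 95% PIs; values below
    1 favor the predicted regimen."""
    fig, ax = plt.subplots(figsize=(6, 0.8 * len(results) + 1.5))
    labels = list(results)
    for i, name in enumerate(labels):
        r = results[name]
        ax.errorbar(
            r.effect, i,
            xerr=[[r.effect - r.pi_lo], [r.pi_hi - r.effect]],
            fmt="s", color="k", capsize=3,
        )
    ax.axvline(1.0, color="grey", ls="--", lw=1)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xscale("log")
    ax.set_xlabel("effect (95% PI), log scale")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
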