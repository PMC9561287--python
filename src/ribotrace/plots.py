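"""Static figures: survival curves, dwell histograms, pathway bars."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .stats import DwellSummary, PathwayMap, SurvivalCurve

__all__ = ["plot_survival", "plot_dwell", "plot_pathway"]


def plot_survival(curves: list[SurvivalCurve], path: str) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for sc in curves:
        ax.plot(
            sc.table["codon"],
            100 * sc.table["fraction"],
            marker="o",
            label=f"{sc.condition} (n={sc.n_total})",
        )
    ax.set_xlabel("codons translated")
    ax.set_ylabel("surviving ribosomes (%)")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dwell(summary: DwellSummary, path: str) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.hist(summary.dwells, bins=30, color="#777", edgecolor="k")
    ax.axvline(summary.mle_mean, color="crimson", label=f"MLE mean {summary.mle_mean:.2f} s")
    ax.set_xlabel("dwell (s)")
    ax.set_ylabel("count")
    ax.set_title(f"{summary.event_class} dwells (n={summary.n})", fontsize=10)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pathway(pm: PathwayMap, path: str) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    keys = ["pre_dis", "post_dis", "survived", "censored"]
    ax.bar(keys, [100 * pm.fractions[k] for k in keys], color="#4878a8")
    ax.set_ylabel("% of suppression-codon decoders")
    ax.set_title(f"{pm.condition} (n={pm.n_decoders})", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
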