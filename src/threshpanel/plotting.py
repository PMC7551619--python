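"""Simple diagnostic plots: BET histograms and fitted threshold lines."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from threshpanel.core_data import DiscriminationDataset, PreferenceDataset
from threshpanel.graphical_method import GraphicalFit
from threshpanel.rejection import RejectionFit, spike_proportions


def plot_bet_histogram(counts: dict[float, int], path: str, title: str = "") -> None:
    """Bar chart of panelist counts per attainable BET value (log x)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    values = sorted(counts)
    ax.bar(range(len(values)), [counts[v] for v in values], color="#777")
    ax.set_xticks(range(len(values)))
    ax.set_xticklabels([f"{v:.3g}" for v in values], rotation=45)
    ax.set_xlabel("best-estimate threshold (ng/L)")
    ax.set_ylabel("panelists")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_graphical_fit(
    data: DiscriminationDataset, fit: GraphicalFit, path: str, include=None
) -> None:
    """Proportion correct vs log10 concentration with the fitted line."""
    records = data.records
    if include is not None:
        include = set(include)
        records = {k: v for k, v in records.items() if k in include}
    logc = np.log10(data.series.levels)
    props = np.mean([[float(o) for o in v] for v in records.values()], axis=0)

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(logc, props, "o", color="k", label="proportion correct")
    xs = np.linspace(logc[0], logc[-1], 100)
    ax.plot(xs, fit.intercept + fit.slope * xs, "-", color="#b33", label="OLS fit")
    ax.axhline(fit.criterion, ls="--", color="#888", label=f"criterion {fit.criterion:.2f}")
    if fit.threshold is not None:
        ax.axvline(np.log10(fit.threshold), ls=":", color="#36c")
    ax.set_xlabel("log10 concentration (ng/L)")
    ax.set_ylabel("proportion correct")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_rejection_fit(data: PreferenceDataset, fit: RejectionFit, path: str, include=None) -> None:
    """Proportion choosing spike vs log10 concentration with the fit."""
    props = spike_proportions(data, include=include)
    logc = np.log10(sorted(props))
    ys = [props[c] for c in sorted(props)]

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(logc, ys, "o", color="k", label="proportion choosing spike")
    xs = np.linspace(logc[0], logc[-1], 100)
    ax.plot(xs, fit.intercept + fit.slope * xs, "-", color="#b33", label="OLS fit")
    for crit, ls in ((0.25, "--"), (0.75, ":")):
        ax.axhline(crit, ls=ls, color="#888")
    ax.set_xlabel("log10 concentration (ng/L)")
    ax.set_ylabel("P(choose spike)")
    ax.set_ylim(-0.05, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
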