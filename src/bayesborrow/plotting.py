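"""Figure helpers: prior/posterior density panels and probability-threshold curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .priors import GaussianPrior, MixturePrior, Prior
from .sampling import PosteriorDraws

__all__ = ["plot_prior_posterior", "plot_threshold_curves"]


def _prior_density(prior: Prior, grid: np.ndarray) -> np.ndarray:
    return np.exp(prior.logpdf(np.log(grid))) / grid   # density on the ratio scale


def plot_prior_posterior(
    priors: dict[str, Prior],
    posteriors: dict[str, PosteriorDraws],
    path: str | Path,
    beta_name: str = "beta",
    xlabel: str = "rate ratio",
) -> Path:
    """Side-by-side densities of priors and the posteriors they lead to."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    grid = np.linspace(0.4, 1.6, 400)
    for name, prior in priors.items():
        axes[0].plot(grid, _prior_density(prior, grid), label=name)
    axes[0].set_title("priors")
    axes[0].legend(fontsize=7)
    for name, draws in posteriors.items():
        rr = np.exp(draws.get(beta_name))
        axes[1].hist(rr, bins=80, density=True, histtype="step", label=name)
    axes[1].set_title("posteriors")
    axes[1].legend(fontsize=7)
    for ax in axes:
        ax.axvline(1.0, color="0.6", lw=0.8, ls="--")
        ax.set_xlabel(xlabel)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_threshold_curves(curves: dict[str, "np.ndarray"], path: str | Path,
                          xlabel: str = "benefit threshold") -> Path:
    """Posterior probability of benefit as a function of the threshold.

    ``curves`` maps a label to a DataFrame with columns threshold/probability.
    """
    fig, ax = plt.subplots(figsize=(5.5, 3.5))
    for name, curve in curves.items():
        ax.plot(curve["threshold"], curve["probability"], label=name)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("posterior probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
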