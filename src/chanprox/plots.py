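"""Minimal figure helpers for the proximity analysis."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_annulus_profile(ensemble, path) -> None:
    """Observed annulus occupancy with the Monte-Carlo null envelope."""
    x = 0.5 * (ensemble.ring_inner_nm + ensemble.ring_outer_nm)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.fill_between(x, ensemble.null_lo, ensemble.null_hi, alpha=0.3,
                    color="tab:orange", label="null 95% envelope")
    ax.plot(x, ensemble.null_mean, "o-", color="tab:orange", ms=3,
            label="randomized")
    ax.plot(x, ensemble.observed_profile, "s-", color="tab:green", ms=3,
            label="observed")
    ax.set_xlabel("distance from reference clusters (nm)")
    ax.set_ylabel("occupied area (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_distance_hist(dist, fit, path, bin_width_nm: float = 20.0) -> None:
    """Nearest edge-to-edge distance histogram with its Gaussian fit."""
    counts, edges = dist.histogram(bin_width_nm)
    centers = 0.5 * (edges[:-1] + edges[1:])
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(centers, counts, width=bin_width_nm * 0.9, color="tab:green",
           alpha=0.7)
    if fit is not None:
        xx = np.linspace(edges[0], edges[-1], 300)
        yy = fit["amplitude"] * np.exp(
            -0.5 * ((xx - fit["peak_nm"]) / fit["sigma_nm"]) ** 2)
        ax.plot(xx, yy, "r-", lw=1.5,
                label=f"peak {fit['peak_nm']:.0f} nm, FWHM {fit['fwhm_nm']:.0f} nm")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("nearest edge-to-edge distance (nm)")
    ax.set_ylabel("clusters")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
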