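"""Optional figures: strand-balance scatter with binomial envelope, end profile."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .strandprofile import EndProfile, EnvelopeConfig


def _mpl():
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    return plt


def plot_strand_balance(rows: pd.DataFrame, basis: str = "total",
                        cfg: EnvelopeConfig = EnvelopeConfig()):
    """Plus vs minus per-nanochromosome counts with the 2-SD binomial envelope."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 5))
    x = rows[f"plus_{basis}"].to_numpy(float)
    y = rows[f"minus_{basis}"].to_numpy(float)
    ax.scatter(x, y, s=6, alpha=0.5, color="black")
    n = np.linspace(max((x + y).min(), 1), (x + y).max(), 400)
    half, d = n / 2, cfg.k_sd * np.sqrt(n) / 2
    ax.plot(half + d, half - d, color="red", lw=1)
    ax.plot(half - d, half + d, color="red", lw=1)
    ax.plot([0, x.max()], [0, x.max()], color="grey", lw=0.5)
    ax.set_xlabel(f"plus-strand reads ({basis})")
    ax.set_ylabel(f"minus-strand reads ({basis})")
    ax.set_xscale("symlog")
    ax.set_yscale("symlog")
    return fig


def plot_end_profile(profile: EndProfile):
    """Binned relative density at both record ends, telomere edge marked."""
    plt = _mpl()
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharey=True)
    binned = profile.binned()
    for ax, end in zip(axes, ("five_prime", "three_prime")):
        sub = binned[binned["end"] == end]
        ax.bar(sub["bin_start"], sub["relative_density"],
               width=profile.cfg.bin, align="edge", color="steelblue")
        ax.axhline(1.0, color="grey", lw=0.8, ls=":")
        ax.axvline(profile.mean_telomere, color="black", lw=0.8, ls="--")
        ax.set_title(f"{end} end, strand {profile.strand}")
        ax.set_xlabel("distance from record end (nt)")
    axes[0].set_ylabel("relative density")
    fig.tight_layout()
    return fig
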