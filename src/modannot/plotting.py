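"""Minimal figure rendering: CI-ribbon line plots and occupancy heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .profiles import BoundaryProfile, MetageneProfile  # noqa: E402


def plot_boundary(profile: BoundaryProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.fill_between(profile.offsets, profile.ci_low, profile.ci_high,
                    alpha=0.25, linewidth=0, label="95% CI")
    ax.plot(profile.offsets, profile.mean_cov, lw=1.2)
    ax.axvline(0, color="grey", lw=0.6, ls="--")
    ax.set_xlabel(f"offset from {profile.anchor} (nt)")
    ax.set_ylabel("mean coverage")
    ax.set_title(f"{profile.anchor} (n={profile.n_units})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metagene(profile: MetageneProfile, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(profile.density, lw=1.2)
    nb = profile.bins_per_region
    for i in range(1, len(profile.region_labels)):
        ax.axvline(i * nb, color="grey", lw=0.6, ls="--")
    centers = [nb * i + nb / 2 for i in range(len(profile.region_labels))]
    ax.set_xticks(centers)
    ax.set_xticklabels([r.upper() for r in profile.region_labels])
    ax.set_ylabel("sites per transcript per bin")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heatmap(matrix, path: str | Path, anchor: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(matrix.to_numpy(), aspect="auto", interpolation="nearest",
              cmap="Reds")
    ax.set_xlabel(f"offset from {anchor} (column index)")
    ax.set_ylabel("transcripts (by occupancy)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
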