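"""Karyotype-style plot exports for the BAF and sex-scan analyses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def baf_karyotype(
    variants,
    phase_blocks,
    scaffold_lengths: dict[str, int],
    path,
    max_scaffolds: int = 10,
) -> None:
    """BAF dots over phase-block rectangles, one row per scaffold."""
    names = sorted(scaffold_lengths, key=scaffold_lengths.get, reverse=True)[:max_scaffolds]
    fig, axes = plt.subplots(len(names), 1, figsize=(10, 1.2 * len(names)), squeeze=False)
    blocks_by = {}
    for scf, s, e in phase_blocks:
        blocks_by.setdefault(scf, []).append((s, e))
    by_scf = {}
    for v in variants:
        by_scf.setdefault(v.scaffold, []).append(v)
    for ax, name in zip(axes[:, 0], names):
        for s, e in blocks_by.get(name, []):
            ax.axvspan(s, e, color="0.85", zorder=0)
        vs = by_scf.get(name, [])
        if vs:
            ax.plot([v.pos for v in vs], [v.baf for v in vs], "k.", ms=1.5, zorder=1)
        ax.set_xlim(0, scaffold_lengths[name])
        ax.set_ylim(0, 1)
        ax.set_ylabel(name, rotation=0, ha="right", va="center", fontsize=7)
        ax.set_yticks([0, 0.5, 1])
        ax.tick_params(labelsize=6)
    axes[-1, 0].set_xlabel("position (bp)")
    fig.suptitle("B-allele frequency and phase blocks")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def depth_ratio_plot(ratios, path) -> None:
    """Windowed male/female depth with the per-scaffold ratio annotated."""
    ratios = [r for r in ratios if r.male_windows.size]
    fig, axes = plt.subplots(len(ratios), 1, figsize=(10, 1.2 * len(ratios)), squeeze=False)
    for ax, r in zip(axes[:, 0], ratios):
        x = np.arange(r.male_windows.size)
        ax.plot(x, r.female_windows, color="black", marker="D", ms=2, lw=0.8, label="female")
        ax.plot(x, r.male_windows, color="purple", lw=1.2, label="male")
        ax.set_ylabel(r.scaffold, rotation=0, ha="right", va="center", fontsize=7)
        ax.text(1.01, 0.5, f"R={r.ratio:.2f}\n{r.call}", transform=ax.transAxes, fontsize=6)
        ax.tick_params(labelsize=6)
    axes[0, 0].legend(fontsize=6, loc="upper right")
    axes[-1, 0].set_xlabel("window index")
    fig.suptitle("male/female mapped depth")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def depth_histograms(report: dict, path) -> None:
    """Single-copy vs duplicated mean-depth histograms with medians marked."""
    hist = report["histogram"]
    edges = np.asarray(hist["bin_edges"])
    mid = (edges[:-1] + edges[1:]) / 2
    fig, axes = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
    for ax, key, med in (
        (axes[0], "single", report["median_single"]),
        (axes[1], "duplicated", report["median_duplicated"]),
    ):
        ax.bar(mid, hist[key], width=(edges[1] - edges[0]) * 0.9, color="steelblue")
        ax.axvline(med, color="red", lw=1)
        ax.text(med, ax.get_ylim()[1] * 0.9, f" {med:.1f}", color="red", fontsize=8)
        ax.set_ylabel(f"{key} genes")
    axes[-1].set_xlabel("mean mapped read depth")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
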