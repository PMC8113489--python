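"""Sex-scaffold identification from male/female windowed depth ratios.

A hemizygous X scaffold receives half the autosomal depth in a male sample
and full depth in a female, so the normalized male/female mean mapped depth
ratio R sits near 0.5 on X-linked scaffolds and near 1.0 on autosomes.
Depth is summarised in fixed non-overlapping windows with terminal windows
removed (scaffold ends taper because fragments cannot overhang them), and
each sample is normalized before the ratio is formed so unequal sequencing
inputs cancel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .placement import DepthTrack

logger = logging.getLogger(__name__)

DEFAULT_X_BAND = (0.35, 0.65)
DEFAULT_AUTOSOME_BAND = (0.8, 1.2)


@dataclass
class ScaffoldRatio:
    scaffold: str
    male_windows: np.ndarray
    female_windows: np.ndarray
    ratio: float  # normalized male/female mean depth; NaN when undefined
    call: str = "unclassified"  # X_linked | autosomal | unclassified


def windowed_depth(
    track: DepthTrack, window: int, drop_terminal: bool = True
) -> dict[str, np.ndarray]:
    """Mean depth in non-overlapping windows of exactly ``window`` bp.

    The trailing partial window is always dropped; with ``drop_terminal`` the
    first and last *full* windows are removed as well.  Scaffolds left with
    no windows yield an empty array (logged).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    out = {}
    for name, depth in track.depths.items():
        n = depth.size // window
        means = depth[: n * window].reshape(n, window).mean(axis=1) if n else np.zeros(0)
        if drop_terminal:
            means = means[1:-1] if n >= 3 else np.zeros(0)
            if n < 3:
                logger.info("scaffold %s shorter than 3 windows; no windows retained", name)
        out[name] = means
    return out


def scaffold_ratio(
    male: DepthTrack,
    female: DepthTrack,
    window: int = 100_000,
    normalization: str = "autosomal_median",
    drop_terminal: bool = True,
) -> list[ScaffoldRatio]:
    """Normalized male/female depth ratio per scaffold.

    ``autosomal_median`` normalizes each sample by the genome-wide median of
    its window means (autosomes dominate, so the median is an autosomal
    depth, robust to the minority of X windows); ``total_bases`` normalizes
    by each sample's genome-wide mean depth, reproducing equal-input
    subsampling.  Scaffolds where the female mean is zero, or with no
    retained windows, are unclassified with ratio NaN.
    """
    if set(male.depths) != set(female.depths):
        raise ValueError("male and female tracks cover different scaffolds")
    mw = windowed_depth(male, window, drop_terminal)
    fw = windowed_depth(female, window, drop_terminal)

    if normalization == "autosomal_median":
        m_all = np.concatenate([v for v in mw.values() if v.size])
        f_all = np.concatenate([v for v in fw.values() if v.size])
        m_norm = float(np.median(m_all))
        f_norm = float(np.median(f_all))
    elif normalization == "total_bases":
        total_len = sum(d.size for d in male.depths.values())
        m_norm = male.total() / total_len
        f_norm = female.total() / total_len
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    out = []
    for name in male.depths:
        m, f = mw[name], fw[name]
        if m.size == 0 or f.size == 0 or f.mean() == 0 or f_norm == 0:
            out.append(ScaffoldRatio(name, m, f, float("nan")))
            continue
        r = (m.mean() / m_norm) / (f.mean() / f_norm)
        out.append(ScaffoldRatio(name, m, f, float(r)))
    return out


def classify_scaffolds(
    ratios: list[ScaffoldRatio],
    x_band: tuple[float, float] = DEFAULT_X_BAND,
    autosome_band: tuple[float, float] = DEFAULT_AUTOSOME_BAND,
) -> list[ScaffoldRatio]:
    """Call scaffolds X_linked / autosomal / unclassified by ratio band."""
    if max(x_band[0], autosome_band[0]) < min(x_band[1], autosome_band[1]):
        raise ValueError("classification bands must be disjoint")
    for sr in ratios:
        if np.isnan(sr.ratio):
            sr.call = "unclassified"
        elif x_band[0] <= sr.ratio <= x_band[1]:
            sr.call = "X_linked"
        elif autosome_band[0] <= sr.ratio <= autosome_band[1]:
            sr.call = "autosomal"
        else:
            sr.call = "unclassified"
    return ratios


def ratios_table(ratios: list[ScaffoldRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scaffold": [r.scaffold for r in ratios],
            "n_windows_male": [r.male_windows.size for r in ratios],
            "n_windows_female": [r.female_windows.size for r in ratios],
            "ratio": [r.ratio for r in ratios],
            "call": [r.call for r in ratios],
        }
    )
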