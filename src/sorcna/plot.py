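"""Simple figures: genome-wide RF frequency tracks and survival step plots."""

from __future__ import annotations

from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .genome import GenomeBuild, chrom_sort_key  # noqa: E402
from .sor import SorProfile  # noqa: E402
from .survival import KmCurve  # noqa: E402

__all__ = ["frequency_track", "km_plot"]


def _genome_offsets(build: GenomeBuild) -> dict[str, int]:
    offsets = {}
    pos = 0
    for chrom, length in build.chromosomes:
        offsets[chrom] = pos
        pos += length
    return offsets


def frequency_track(profiles: Mapping[str, SorProfile], build: GenomeBuild,
                    ax: Optional[plt.Axes] = None) -> plt.Figure:
    """Gain RFs plotted upward, loss RFs downward along the genome."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(14, 3.5))
    else:
        fig = ax.figure
    offsets = _genome_offsets(build)
    colors = {"gain": "tab:blue", "loss": "tab:red"}
    signs = {"gain": 1.0, "loss": -1.0}
    for direction, profile in profiles.items():
        for seg in profile.of_direction(direction):
            x0 = offsets[seg.chromosome] + seg.start
            ax.fill_between(
                [x0, x0 + seg.length], 0, signs[direction] * seg.rf,
                color=colors[direction], linewidth=0,
            )
    for chrom, off in offsets.items():
        ax.axvline(off, color="0.85", linewidth=0.5)
    ax.set_ylim(-1, 1)
    ax.set_ylabel("relative frequency\n(loss down / gain up)")
    ax.set_xticks(
        [offsets[c] + length / 2 for c, length in build.chromosomes]
    )
    ax.set_xticklabels(
        [c.removeprefix("chr") for c, _ in build.chromosomes], fontsize=7
    )
    ax.axhline(0, color="black", linewidth=0.7)
    fig.tight_layout()
    return fig


def km_plot(curves: Mapping[str, KmCurve], ax: Optional[plt.Axes] = None) -> plt.Figure:
    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 4))
    else:
        fig = ax.figure
    for label, curve in curves.items():
        xs = [0.0]
        ys = [1.0]
        for t, s in zip(curve.times, curve.survival):
            xs.extend([t, t])
            ys.extend([ys[-1], s])
        ax.plot(xs, ys, drawstyle="default", label=label)
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
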