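"""Sliding-window mapping statistics and candidate region calling.

The filtered marker set is summarised in overlapping windows tiled along each
autosome (default 20 Mb windows advancing in 1 Mb steps).  Three statistics
are computed per window from the pooled per-site allele fractions:

* ``hom_count`` — number of markers classed homozygous (site NAF at or above
  a cutoff, 0.9 by default);
* ``hom_pct``   — the same as a percentage of the window's markers;
* ``avg_naf``   — the mean non-reference allele frequency.

At the causal locus every pooled chromosome carries the mutant haplotype, so
the recombinant interval stands out as a run of windows with NAF near 1 and
homozygote percentage near 100, against an unlinked background of ~50 % NAF
(carrier dams) and ~12.5 % per-mouse homozygosity.  Qualifying windows are
merged into candidate :class:`MappingRegion` intervals under either the
homozygosity criterion (hom_pct) or the novel-allele-frequency fallback
criterion (avg_naf), mirroring the two mapping strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .variant_model import GenomeLayout, Variant

__all__ = [
    "MappingRegion",
    "Window",
    "WindowConfig",
    "call_zygosity",
    "find_regions",
    "make_windows",
    "plot_tracks",
    "score_windows",
    "windows_to_tsv",
    "regions_to_bed",
]


@dataclass(frozen=True)
class WindowConfig:
    """Window geometry and zygosity-classification parameters.

    ``size`` is one of the method's window sizes (2/5/10/20 Mb).  ``step`` is
    the slide between consecutive window starts; with the default 1 Mb step a
    20 Mb window overlaps its successor by 19 Mb.  ``hom_naf_threshold`` is
    the pooled-NAF cutoff above which a site is classed homozygous.
    ``min_snps`` guards region calling against variant-sparse windows.
    """

    size: int = 20_000_000
    step: int = 1_000_000
    hom_naf_threshold: float = 0.9
    min_snps: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.size:
            raise ValueError("require 0 < step <= size")
        if not 0 < self.hom_naf_threshold <= 1:
            raise ValueError("hom_naf_threshold must lie in (0, 1]")


@dataclass
class Window:
    """A genomic window with its three mapping metrics.

    Metrics are ``None`` until scored, and stay ``None`` (undefined) for
    windows containing no markers.
    """

    chrom: str
    start: int  # 0-based half-open
    end: int
    n_snps: int = 0
    hom_count: int = 0
    hom_pct: float | None = None
    avg_naf: float | None = None


@dataclass(frozen=True)
class MappingRegion:
    """Merged run of threshold-passing windows — a candidate recombinant
    interval containing the mutation."""

    chrom: str
    start: int
    end: int
    criterion: Literal["homozygosity", "naf"]
    n_windows: int
    n_snps: int
    peak_value: float

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


def call_zygosity(variant: Variant, hom_naf_threshold: float = 0.9) -> str:
    """Class a pooled site as ``"hom"`` or ``"het"`` by its NAF.

    The pooled library carries no per-mouse genotypes, so zygosity is defined
    from the read fraction: hom iff naf >= threshold (boundary inclusive).
    Requires read coverage; the default pipeline guarantees depth >= 5.
    """
    if variant.depth == 0:
        raise ValueError(f"{variant.chrom}:{variant.pos}: zygosity undefined at depth 0")
    return "hom" if variant.naf >= hom_naf_threshold else "het"


def make_windows(layout: GenomeLayout, cfg: WindowConfig = WindowConfig()) -> list[Window]:
    """Tile each autosome with sliding windows.

    Starts are 0, step, 2*step, ...; the final window is truncated at the
    chromosome end, and generation stops once a window reaches it, so every
    autosomal bp is covered by at least one window.  A chromosome shorter
    than the window size yields the single window [0, length).
    """
    windows: list[Window] = []
    for chrom, length in layout.autosomes():
        start = 0
        while True:
            end = min(start + cfg.size, length)
            windows.append(Window(chrom=chrom, start=start, end=end))
            if end >= length:
                break
            start += cfg.step
    return windows


def score_windows(
    variants: Sequence[Variant],
    windows: Sequence[Window],
    cfg: WindowConfig = WindowConfig(),
) -> list[Window]:
    """Fill the three metrics for windows produced by :func:`make_windows`.

    Every variant contributes to each window containing its 0-based
    coordinate.  Windows with no variants keep undefined metrics.  Runs in
    O(V + W) per chromosome via difference arrays over the regular window
    grid.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)

    out = [replace(w, n_snps=0, hom_count=0, hom_pct=None, avg_naf=None) for w in windows]
    step, size = cfg.step, cfg.size

    for chrom, idxs in by_chrom.items():
        starts = np.array([windows[i].start for i in idxs])
        if not np.array_equal(starts, np.arange(len(idxs)) * step):
            raise ValueError("windows do not form a regular grid; use make_windows")
        k_max = len(idxs) - 1
        vs = [v for v in variants if v.chrom == chrom]
        if not vs:
            continue
        for v in vs:
            if v.depth == 0:
                raise ValueError(f"{v.chrom}:{v.pos}: unscoreable variant with depth 0")
        pos0 = np.array([v.pos0 for v in vs])
        naf = np.array([v.naf for v in vs])
        hom = (naf >= cfg.hom_naf_threshold).astype(float)
        k_hi = np.minimum(pos0 // step, k_max)
        k_lo = np.maximum(0, -((size - pos0 - 1) // step))  # ceil((pos0-size+1)/step)
        n_diff = np.zeros(len(idxs) + 1)
        h_diff = np.zeros(len(idxs) + 1)
        s_diff = np.zeros(len(idxs) + 1)
        np.add.at(n_diff, k_lo, 1)
        np.add.at(n_diff, k_hi + 1, -1)
        np.add.at(h_diff, k_lo, hom)
        np.add.at(h_diff, k_hi + 1, -hom)
        np.add.at(s_diff, k_lo, naf)
        np.add.at(s_diff, k_hi + 1, -naf)
        n = np.cumsum(n_diff)[:-1]
        h = np.cumsum(h_diff)[:-1]
        s = np.cumsum(s_diff)[:-1]
        for k, i in enumerate(idxs):
            cnt = int(round(n[k]))
            out[i].n_snps = cnt
            out[i].hom_count = int(round(h[k]))
            if cnt > 0:
                out[i].hom_pct = 100.0 * out[i].hom_count / cnt
                out[i].avg_naf = float(s[k]) / cnt
    return out


def find_regions(
    windows: Sequence[Window],
    criterion: Literal["homozygosity", "naf"],
    threshold: float,
    cfg: WindowConfig = WindowConfig(),
) -> list[MappingRegion]:
    """Merge threshold-passing windows into candidate regions.

    A window qualifies iff it holds at least ``cfg.min_snps`` markers and its
    metric (hom_pct for ``homozygosity``, in percent; avg_naf for ``naf``, as
    a fraction) strictly exceeds ``threshold``.  Qualifying windows that
    overlap or abut on a chromosome merge into one region spanning their
    union.  Regions are sorted by descending peak metric, ties in genome
    order (order of first appearance in ``windows``).
    """
    if criterion == "homozygosity":
        metric = lambda w: w.hom_pct
    elif criterion == "naf":
        metric = lambda w: w.avg_naf
    else:
        raise ValueError(f"unknown criterion {criterion!r}")

    chrom_order: dict[str, int] = {}
    for w in windows:
        chrom_order.setdefault(w.chrom, len(chrom_order))

    qualifying = [
        w
        for w in windows
        if w.n_snps >= cfg.min_snps and metric(w) is not None and metric(w) > threshold
    ]
    qualifying.sort(key=lambda w: (chrom_order[w.chrom], w.start, w.end))

    regions: list[MappingRegion] = []
    run: list[Window] = []

    def close_run() -> None:
        if not run:
            return
        regions.append(
            MappingRegion(
                chrom=run[0].chrom,
                start=run[0].start,
                end=max(w.end for w in run),
                criterion=criterion,
                n_windows=len(run),
                n_snps=max(w.n_snps for w in run),
                peak_value=max(metric(w) for w in run),
            )
        )

    for w in qualifying:
        if run and w.chrom == run[-1].chrom and w.start <= max(r.end for r in run):
            run.append(w)
        else:
            close_run()
            run = [w]
    close_run()
    regions.sort(key=lambda r: (-r.peak_value, chrom_order[r.chrom], r.start))
    return regions


def plot_tracks(
    windows: Sequence[Window],
    layout: GenomeLayout,
    path: str | Path,
) -> dict:
    """Three-track genome plot (avg_naf, hom_count, hom_pct) over the
    concatenated autosomes.

    Windows with no markers are dropped rather than drawn at zero, to avoid
    fake troughs.  Returns metadata including, per metric, the chromosome
    holding the peak window.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    offsets: dict[str, int] = {}
    running = 0
    for chrom, length in layout.autosomes():
        offsets[chrom] = running
        running += length

    metrics = [("avg_naf", "average naf"), ("hom_count", "hom count"), ("hom_pct", "hom percentage")]
    fig, axes = plt.subplots(3, 1, figsize=(12, 7), sharex=True)
    meta: dict = {"peak_chrom": {}, "n_windows_plotted": 0}
    plotted = 0
    for (attr, label), ax in zip(metrics, axes):
        xs, ys, chroms = [], [], []
        for w in windows:
            if w.n_snps == 0 or w.chrom not in offsets:
                continue
            val = getattr(w, attr)
            if val is None:
                continue
            xs.append(offsets[w.chrom] + (w.start + w.end) / 2)
            ys.append(val)
            chroms.append(w.chrom)
        if xs:
            ax.plot(xs, ys, ".", markersize=2)
            meta["peak_chrom"][attr] = chroms[int(np.argmax(ys))]
            plotted = max(plotted, len(xs))
        for chrom, off in offsets.items():
            ax.axvline(off, color="0.85", linewidth=0.5)
        ax.set_ylabel(label)
    axes[-1].set_xlabel("concatenated autosome position (bp)")
    meta["n_windows_plotted"] = plotted
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return meta


def windows_to_tsv(windows: Sequence[Window], path: str | Path) -> None:
    """Write scored windows as a TSV (undefined metrics as ``NA``)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_snps\thom_count\thom_pct\tavg_naf\n")
        for w in windows:
            hp = "NA" if w.hom_pct is None else f"{w.hom_pct:.4f}"
            an = "NA" if w.avg_naf is None else f"{w.avg_naf:.6f}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_snps}\t{w.hom_count}\t{hp}\t{an}\n")


def regions_to_bed(regions: Sequence[MappingRegion], path: str | Path) -> None:
    """Write regions as BED: name = criterion, score = peak_value * 1000."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.criterion}\t{r.peak_value * 1000:.0f}\n"
            )
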