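"""Insulation scores and TAD border calling.

The insulation score of bin *i* is the mean balanced contact over the square
window of pairs (a, b) with i-w <= a < i < b <= i+w (w bins each side); it is
normalised per chromosome as log2 of the window mean over the chromosome mean
of window means, so a global rescaling of the map cancels. Scores are defined
only where the full window fits inside the chromosome and at least half of
the window cells are unmasked. Borders are local minima of the score with a
topographic prominence above a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .genome import GenomeSpec
from .hic import ContactMap

__all__ = ["InsulationTrack", "insulation_score", "call_borders", "border_overlap"]


@dataclass
class InsulationTrack:
    """Per-bin raw window mean and normalised insulation score (IS)."""

    genome: GenomeSpec
    window: int
    raw: np.ndarray     # window means, NaN where undefined
    score: np.ndarray   # log2(window mean / chromosome mean of window means)

    def to_bedgraph(self, path) -> None:
        df = self.genome.bin_table()
        df["score"] = self.score
        df.dropna(subset=["score"]).to_csv(path, sep="\t", header=False, index=False,
                                           float_format="%.6g")


def insulation_score(cmap: ContactMap, window: int = 100_000,
                     min_valid_frac: float = 0.5) -> InsulationTrack:
    """Diamond-window insulation score on a balanced map.

    ``window`` (bp) must be a multiple of the map resolution. Chromosomes
    shorter than ``2*w + 1`` bins are all-NA; so are the first/last ``w``
    bins, masked bins, and bins whose window has fewer than
    ``min_valid_frac`` unmasked cells.
    """
    if window % cmap.resolution:
        raise ValueError("window must be a multiple of the map resolution")
    w = window // cmap.resolution
    if w < 1:
        raise ValueError("window smaller than one bin")
    raw = np.full(cmap.genome.n_bins, np.nan)
    score = np.full(cmap.genome.n_bins, np.nan)
    for chrom, (lo, hi) in cmap.genome.chrom_bounds().items():
        n = hi - lo
        if n < 2 * w + 1:
            continue
        bal = cmap.balanced(chrom)
        means = np.full(n, np.nan)
        for i in range(w, n - w):
            if cmap.mask[lo + i]:
                continue
            block = bal[i - w : i, i + 1 : i + w + 1]
            valid = np.isfinite(block)
            if valid.sum() < min_valid_frac * block.size:
                continue
            means[i] = block[valid].mean()
        ok = np.isfinite(means)
        if ok.any():
            chrom_mean = means[ok].mean()
            if chrom_mean > 0:
                with np.errstate(divide="ignore"):
                    score[lo:hi][ok] = np.log2(means[ok] / chrom_mean)
        raw[lo:hi] = means
    return InsulationTrack(cmap.genome, window, raw, score)


def call_borders(track: InsulationTrack, min_prominence: float = 0.2) -> pd.DataFrame:
    """Local minima of the insulation score with prominence >= threshold.

    Runs per chromosome on each contiguous stretch of defined scores.
    Returns a DataFrame ``chrom, start, bin, score, prominence`` ordered by
    genomic position (``bin`` is the global bin index).
    """
    rows = []
    res = track.genome.bin_size
    for chrom, (lo, hi) in track.genome.chrom_bounds().items():
        s = track.score[lo:hi]
        defined = np.isfinite(s)
        # split into contiguous defined segments
        edges = np.flatnonzero(np.diff(defined.astype(int)) != 0) + 1
        for seg in np.split(np.arange(s.size), edges):
            if seg.size < 3 or not defined[seg[0]]:
                continue
            vals = s[seg]
            peaks, props = find_peaks(-vals, prominence=min_prominence)
            for p, prom in zip(peaks, props["prominences"]):
                i = seg[p]
                rows.append((chrom, i * res, lo + i, s[i], prom))
    return pd.DataFrame(rows, columns=["chrom", "start", "bin", "score", "prominence"])


def border_overlap(borders_a: pd.DataFrame, borders_b: pd.DataFrame,
                   tolerance: int = 20_000):
    """Fraction of A borders with a B border within ±tolerance (inclusive).

    Matching is greedy one-to-one in genomic order: each A border takes the
    nearest still-unused B border within tolerance on the same chromosome.
    Returns ``(fraction, matches)`` where ``matches`` is a DataFrame of
    matched pairs; the fraction is NaN when A is empty.
    """
    matches = []
    used: set[tuple[str, int]] = set()
    b_by_chrom = {
        chrom: np.sort(sub["start"].to_numpy())
        for chrom, sub in borders_b.groupby("chrom")
    }
    a_sorted = borders_a.sort_values(["chrom", "start"], kind="stable")
    for chrom, start in a_sorted[["chrom", "start"]].itertuples(index=False):
        cand = b_by_chrom.get(chrom)
        if cand is None:
            continue
        dist = np.abs(cand - start)
        order = np.argsort(dist, kind="stable")
        for k in order:
            if dist[k] > tolerance:
                break
            key = (chrom, int(cand[k]))
            if key not in used:
                used.add(key)
                matches.append((chrom, int(start), int(cand[k]), int(dist[k])))
                break
    n_a = len(borders_a)
    frac = float("nan") if n_a == 0 else len(matches) / n_a
    return frac, pd.DataFrame(matches, columns=["chrom", "start_a", "start_b", "distance"])
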