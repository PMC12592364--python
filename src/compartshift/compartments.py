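"""A/B compartment calling, switching classification and saddle analysis.

Compartments are called per chromosome in cis: the Pearson correlation matrix
of observed-over-expected columns is double-centred and its leading
eigenvector (largest absolute eigenvalue, scaled by sqrt of that eigenvalue)
gives the EV1 track. The sign is oriented so EV1 correlates positively with
GC content; positive EV1 is compartment A, negative is B.

A compartment-switching bin is one whose EV1 sign changes in the same
direction between two conditions in *both* replicate cell lines; bins whose
sign change is discordant across lines count as unchanged. The genome
switching proportion is taken over all bins with defined EV1 in all four
tracks.

Saddle analysis splits the EV1 signal into equal-count percentile groups and
averages O/E per group pair, from lowest (most strongly B) to highest (most
strongly A); corner means quantify compartmentalisation strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .hic import ContactMap
from .tracks import BinnedTrack

__all__ = [
    "CompartmentTrack",
    "SwitchCall",
    "SaddleMatrix",
    "compute_ev1",
    "call_domains",
    "classify_switch_bins",
    "saddle",
    "differential_saddle",
    "domain_enrichment_stack",
]


@dataclass
class CompartmentTrack:
    """Per-bin EV1 value with derived A/B/NA labels."""

    genome: GenomeSpec
    ev1: np.ndarray  # NaN where undefined

    def __post_init__(self) -> None:
        self.ev1 = np.asarray(self.ev1, dtype=float)
        if self.ev1.shape != (self.genome.n_bins,):
            raise ValueError("ev1 length does not match bin table")

    @property
    def labels(self) -> np.ndarray:
        """'A' where EV1 > 0, 'B' where EV1 < 0, 'NA' where undefined or exactly 0."""
        lab = np.full(self.ev1.shape, "NA", dtype=object)
        lab[np.isfinite(self.ev1) & (self.ev1 > 0)] = "A"
        lab[np.isfinite(self.ev1) & (self.ev1 < 0)] = "B"
        return lab

    def to_bedgraph(self, path) -> None:
        df = self.genome.bin_table()
        df["ev1"] = self.ev1
        df.dropna(subset=["ev1"]).to_csv(path, sep="\t", header=False, index=False,
                                         float_format="%.6g")


def compute_ev1(oe_map: ContactMap, gc: BinnedTrack, min_bins: int = 10) -> CompartmentTrack:
    """EV1 compartment track from an O/E map, sign-oriented by GC content.

    Per chromosome, columns of the O/E matrix restricted to usable bins
    (unmasked, at least one finite off-diagonal entry) are correlated; the
    correlation matrix is double-centred and decomposed; the eigenvector with
    the largest absolute eigenvalue, scaled by sqrt(|eigenvalue|), is EV1.
    The sign is flipped so that Pearson correlation with GC is non-negative.
    Chromosomes with fewer than ``min_bins`` usable bins are all-NA.
    """
    if oe_map.kind != "oe":
        raise ValueError("compute_ev1 expects an O/E map")
    if gc.genome != oe_map.genome:
        raise ValueError("GC track is not on the map's bins")
    ev = np.full(oe_map.genome.n_bins, np.nan)
    bounds = oe_map.genome.chrom_bounds()
    for chrom in oe_map.genome.chrom_names:
        lo, hi = bounds[chrom]
        m = oe_map.matrices[chrom]
        usable = ~oe_map.mask[lo:hi] & (np.isfinite(m).sum(axis=1) > 1)
        idx = np.flatnonzero(usable)
        if idx.size < min_bins:
            continue
        sub = m[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.nan)
        sub[~np.isfinite(sub)] = 1.0  # neutral fill for undefined O/E entries
        corr = np.corrcoef(sub, rowvar=False)
        corr[~np.isfinite(corr)] = 0.0
        # double-centre before decomposition
        rm = corr.mean(axis=0, keepdims=True)
        cm = corr.mean(axis=1, keepdims=True)
        centred = corr - rm - cm + corr.mean()
        vals, vecs = np.linalg.eigh(centred)
        k = int(np.argmax(np.abs(vals)))
        vec = vecs[:, k] * np.sqrt(np.abs(vals[k]))
        gvals = gc.values[lo:hi][idx]
        ok = np.isfinite(gvals)
        if ok.sum() >= 2 and np.std(vec[ok]) > 0 and np.std(gvals[ok]) > 0:
            r = np.corrcoef(vec[ok], gvals[ok])[0, 1]
            if r < 0:
                vec = -vec
        ev[lo + idx] = vec
    return CompartmentTrack(oe_map.genome, ev)


def call_domains(track: CompartmentTrack) -> pd.DataFrame:
    """Maximal runs of same-sign bins as A/B domains.

    Returns a DataFrame with ``chrom, start, end, sign, size`` (bp). NA bins
    break runs and belong to no domain.
    """
    rows = []
    labels = track.labels
    res = track.genome.bin_size
    for chrom, (lo, hi) in track.genome.chrom_bounds().items():
        lab = labels[lo:hi]
        i = 0
        n = hi - lo
        while i < n:
            if lab[i] == "NA":
                i += 1
                continue
            j = i
            while j + 1 < n and lab[j + 1] == lab[i]:
                j += 1
            start = i * res
            end = min((j + 1) * res, track.genome.sizes[chrom])
            rows.append((chrom, start, end, lab[i], end - start))
            i = j + 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "sign", "size"])


@dataclass
class SwitchCall:
    """Per-bin concordant switching labels and genome proportions."""

    genome: GenomeSpec
    labels: np.ndarray  # 'A-to-B' | 'B-to-A' | 'unchanged' | 'NA'

    def counts(self) -> dict[str, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        out = {k: 0 for k in ("A-to-B", "B-to-A", "unchanged", "NA")}
        out.update(dict(zip(lab, cnt.astype(int))))
        return out

    @property
    def n_scored(self) -> int:
        return int((self.labels != "NA").sum())

    def proportion(self, direction: str | None = None) -> float:
        """Fraction of scored (non-NA) bins switching; optionally one direction."""
        if self.n_scored == 0:
            return float("nan")
        c = self.counts()
        num = c["A-to-B"] + c["B-to-A"] if direction is None else c[direction]
        return num / self.n_scored


def classify_switch_bins(
    ev_wt_line1: CompartmentTrack,
    ev_ko_line1: CompartmentTrack,
    ev_wt_line2: CompartmentTrack,
    ev_ko_line2: CompartmentTrack,
) -> SwitchCall:
    """Concordant per-bin compartment switching between two conditions.

    A bin is A-to-B iff EV1 > 0 in the first condition and < 0 in the second
    in BOTH cell lines (B-to-A symmetric). Any NA or zero among the four
    values makes the bin NA; a sign change in only one line is 'unchanged'.
    """
    tracks = (ev_wt_line1, ev_ko_line1, ev_wt_line2, ev_ko_line2)
    genome = ev_wt_line1.genome
    for t in tracks[1:]:
        if t.genome != genome:
            raise ValueError("the four EV1 tracks are on different bin tables")
    e = np.stack([t.ev1 for t in tracks])
    defined = np.isfinite(e).all(axis=0) & (e != 0).all(axis=0)
    a2b = (e[0] > 0) & (e[1] < 0) & (e[2] > 0) & (e[3] < 0)
    b2a = (e[0] < 0) & (e[1] > 0) & (e[2] < 0) & (e[3] > 0)
    labels = np.full(genome.n_bins, "NA", dtype=object)
    labels[defined] = "unchanged"
    labels[defined & a2b] = "A-to-B"
    labels[defined & b2a] = "B-to-A"
    return SwitchCall(genome, labels)


@dataclass
class SaddleMatrix:
    """Mean O/E per EV1-percentile pair, lowest (B) to highest (A)."""

    grid: np.ndarray      # (q, q) mean O/E
    counts: np.ndarray    # pairs per cell
    sumsq: np.ndarray     # for standard errors

    @property
    def n_quantiles(self) -> int:
        return self.grid.shape[0]

    def se(self) -> np.ndarray:
        """Per-cell standard error of the mean O/E."""
        with np.errstate(divide="ignore", invalid="ignore"):
            var = self.sumsq / self.counts - self.grid**2
            var = np.clip(var, 0, None)
            return np.sqrt(var / np.maximum(self.counts - 1, 1)) * np.where(
                self.counts > 1, 1.0, np.nan
            )

    def corner_mean(self, corner: str, size: int = 5) -> float:
        """Weighted mean O/E of a corner block: 'BB', 'AA', or 'AB'."""
        q = self.n_quantiles
        blocks = {
            "BB": (slice(0, size), slice(0, size)),
            "AA": (slice(q - size, q), slice(q - size, q)),
            "AB": (slice(q - size, q), slice(0, size)),
        }
        sl = blocks[corner.upper()]
        c = self.counts[sl]
        if c.sum() == 0:
            return float("nan")
        return float(np.nansum(self.grid[sl] * c) / c.sum())


def _quantile_groups(values: np.ndarray, n_quantiles: int) -> np.ndarray:
    """Equal-count group assignment; ties broken by position (stable sort)."""
    order = np.argsort(values, kind="stable")
    groups = np.empty(values.size, dtype=np.int64)
    groups[order] = (np.arange(values.size) * n_quantiles) // values.size
    return groups


def saddle(
    oe_map: ContactMap,
    track: CompartmentTrack,
    n_quantiles: int = 50,
    trim: tuple[float, float] | None = None,
) -> SaddleMatrix:
    """Average O/E within EV1 percentile pairs, aggregated genome-wide.

    Bins with defined EV1 (optionally trimmed to the ``trim`` EV1-quantile
    range) are split into ``n_quantiles`` equal-count groups; per chromosome,
    off-diagonal O/E values are accumulated per group pair and combined
    genome-wide weighted by pair counts. The grid is symmetrised.
    """
    if track.genome != oe_map.genome:
        raise ValueError("EV1 track and O/E map are on different bins")
    ev = track.ev1.copy()
    ev[oe_map.mask] = np.nan
    usable = np.isfinite(ev)
    if trim is not None:
        lo_q, hi_q = np.nanquantile(ev[usable], trim)
        usable &= (ev >= lo_q) & (ev <= hi_q)
    if usable.sum() < n_quantiles:
        raise ValueError(
            f"only {int(usable.sum())} usable bins for {n_quantiles} quantile groups"
        )
    groups = np.full(ev.size, -1, dtype=np.int64)
    groups[usable] = _quantile_groups(ev[usable], n_quantiles)
    sums = np.zeros((n_quantiles, n_quantiles))
    counts = np.zeros((n_quantiles, n_quantiles), dtype=np.int64)
    sumsq = np.zeros((n_quantiles, n_quantiles))
    for chrom, (lo, hi) in oe_map.genome.chrom_bounds().items():
        g = groups[lo:hi]
        idx = np.flatnonzero(g >= 0)
        if idx.size < 2:
            continue
        sub = oe_map.matrices[chrom][np.ix_(idx, idx)]
        gi = g[idx]
        iu, ju = np.triu_indices(idx.size, k=1)
        vals = sub[iu, ju]
        ok = np.isfinite(vals)
        np.add.at(sums, (gi[iu[ok]], gi[ju[ok]]), vals[ok])
        np.add.at(sumsq, (gi[iu[ok]], gi[ju[ok]]), vals[ok] ** 2)
        np.add.at(counts, (gi[iu[ok]], gi[ju[ok]]), 1)
    sums = sums + sums.T - np.diag(np.diag(sums))
    sumsq = sumsq + sumsq.T - np.diag(np.diag(sumsq))
    counts = counts + counts.T - np.diag(np.diag(counts))
    with np.errstate(invalid="ignore"):
        grid = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return SaddleMatrix(grid, counts, sumsq)


def differential_saddle(saddle_a: SaddleMatrix, saddle_b: SaddleMatrix) -> np.ndarray:
    """Element-wise log2(B/A) of two saddle grids; empty cells are NaN."""
    if saddle_a.grid.shape != saddle_b.grid.shape:
        raise ValueError("saddle grids have different sizes")
    a, b = saddle_a.grid, saddle_b.grid
    ok = (saddle_a.counts > 0) & (saddle_b.counts > 0) & (a > 0) & (b > 0)
    out = np.full(a.shape, np.nan)
    out[ok] = np.log2(b[ok] / a[ok])
    return out


def domain_enrichment_stack(
    domains: pd.DataFrame,
    track: BinnedTrack,
    flank: int = 2_500_000,
    min_size: int | None = None,
):
    """Stack a signal track over domains, centred at their midpoints.

    One row per domain (± ``flank`` bp around the midpoint bin), rows sorted
    by domain size descending; out-of-chromosome cells are NaN. Returns
    ``(matrix, sorted_domains)`` where ``sorted_domains`` is the reordered
    (and optionally size-filtered) domain table.
    """
    from .sites import _stack_intervals  # shared stacking core

    dom = domains.copy()
    if min_size is not None:
        dom = dom[dom["size"] >= min_size]
    dom = dom.sort_values("size", ascending=False, kind="stable").reset_index(drop=True)
    mat = _stack_intervals(track, dom, flank)
    return mat, dom
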