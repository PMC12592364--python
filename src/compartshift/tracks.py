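"""Binned coverage tracks and their normalisation pipeline.

A :class:`BinnedTrack` is a per-bin numeric signal on a genome's bin table,
tagged with the unit it currently carries. The tags enforce the processing
order used for sequencing coverage: raw fragment ``counts`` are aggregated to
coarser bins, converted to ``cpm`` (counts per million), IP tracks are divided
by their matched input (``log2_ratio``), and finally scaled and centred per
chromosome (``zscore``). RNA coverage takes the ``log2_cpm1`` branch instead.
Missing data is NaN and propagates; zeros in either IP or input make the log
ratio missing rather than being patched with a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import GenomeSpec

__all__ = [
    "BinnedTrack",
    "bin_fragments",
    "rebin",
    "cpm_normalize",
    "log2_ip_over_input",
    "zscore_per_chromosome",
    "smooth_nonzero",
    "rna_log_cpm",
]

UNITS = ("counts", "cpm", "log2_ratio", "zscore", "log2_cpm1", "gc")


@dataclass
class BinnedTrack:
    """Per-bin signal with missing-data support.

    ``values`` is aligned with ``genome.bin_table()`` (global bin order);
    NaN marks missing bins. ``units`` is one of ``counts``, ``cpm``,
    ``log2_ratio``, ``zscore``, ``log2_cpm1``.
    """

    genome: GenomeSpec
    values: np.ndarray
    units: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.n_bins,):
            raise ValueError(
                f"values length {self.values.shape} does not match {self.genome.n_bins} bins"
            )
        if self.units not in UNITS:
            raise ValueError(f"unknown unit tag {self.units!r}")

    @property
    def resolution(self) -> int:
        return self.genome.bin_size

    def bin_table(self) -> pd.DataFrame:
        df = self.genome.bin_table()
        df["value"] = self.values
        return df

    def per_chromosome(self):
        """Yield ``(chrom, view_of_values)`` in genome order."""
        for chrom, (lo, hi) in self.genome.chrom_bounds().items():
            yield chrom, self.values[lo:hi]

    def copy(self) -> "BinnedTrack":
        return replace(self, values=self.values.copy())

    # bedGraph round-trip ---------------------------------------------------

    def to_bedgraph(self, path) -> None:
        df = self.bin_table().dropna(subset=["value"])
        df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")

    @classmethod
    def from_bedgraph(cls, path, genome: GenomeSpec, units: str = "counts") -> "BinnedTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
            dtype={"chrom": str}, comment="#",
        )
        values = np.full(genome.n_bins, np.nan)
        off = genome.chrom_offsets()
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in off:
                raise ValueError(f"bedGraph names unknown chromosome {chrom!r}")
            idx = off[chrom] + sub["start"].to_numpy() // genome.bin_size
            values[idx] = sub["value"].to_numpy()
        return cls(genome, values, units)


def _require_units(track: BinnedTrack, *allowed: str) -> None:
    if track.units not in allowed:
        raise ValueError(f"operation expects units in {allowed}, got {track.units!r}")


def _require_same_bins(a: BinnedTrack, b: BinnedTrack) -> None:
    if a.genome != b.genome:
        raise ValueError("tracks are on different bin tables")


def bin_fragments(fragments: pd.DataFrame, genome: GenomeSpec, resolution: int | None = None):
    """Count fragments into bins; each fragment lands in the bin holding its midpoint.

    Parameters
    ----------
    fragments
        DataFrame with ``chrom``, ``start``, ``end`` columns (0-based half-open).
    genome
        Genome at the counting resolution (or pass ``resolution`` to rebin it).

    Returns
    -------
    (BinnedTrack, int)
        The counts track and the number of fragments skipped because their
        midpoint fell outside a known chromosome.
    """
    if resolution is not None and resolution != genome.bin_size:
        genome = genome.with_bin_size(resolution)
    counts = np.zeros(genome.n_bins)
    off = genome.chrom_offsets()
    sizes = genome.sizes
    skipped = 0
    for chrom, sub in fragments.groupby("chrom", sort=False):
        mid = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        if chrom not in off:
            skipped += len(sub)
            continue
        ok = (mid >= 0) & (mid < sizes[chrom])
        skipped += int((~ok).sum())
        idx = off[chrom] + mid[ok] // genome.bin_size
        np.add.at(counts, idx, 1)
    return BinnedTrack(genome, counts, "counts"), skipped


def rebin(track: BinnedTrack, target: int = 10_000) -> BinnedTrack:
    """Aggregate a counts track to a coarser resolution by summing.

    Only ``counts`` tracks may be rebinned: normalisation happens after
    aggregation. The target must be a multiple of the source resolution.
    """
    _require_units(track, "counts")
    if target == track.resolution:
        return track.copy()
    if target % track.resolution != 0:
        raise ValueError(f"target {target} is not a multiple of resolution {track.resolution}")
    factor = target // track.resolution
    coarse = track.genome.with_bin_size(target)
    out = np.zeros(coarse.n_bins)
    bounds = track.genome.chrom_bounds()
    cbounds = coarse.chrom_bounds()
    for chrom in track.genome.chrom_names:
        lo, hi = bounds[chrom]
        clo, chi = cbounds[chrom]
        vals = track.values[lo:hi]
        groups = np.arange(hi - lo) // factor
        out[clo:chi] = np.bincount(groups, weights=np.nan_to_num(vals), minlength=chi - clo)
    return BinnedTrack(coarse, out, "counts")


def cpm_normalize(track: BinnedTrack, library_total: float | None = None) -> BinnedTrack:
    """Scale counts to counts per million.

    ``library_total`` overrides the default denominator (the track sum) when
    the total number of mapped fragments is known externally.
    """
    _require_units(track, "counts")
    total = float(np.nansum(track.values)) if library_total is None else float(library_total)
    if total <= 0:
        raise ValueError("library total must be positive")
    return BinnedTrack(track.genome, track.values * 1e6 / total, "cpm")


def log2_ip_over_input(ip: BinnedTrack, input_: BinnedTrack) -> BinnedTrack:
    """log2(IP/input) per bin; bins where either side is zero or missing become NaN."""
    _require_units(ip, "cpm")
    _require_units(input_, "cpm")
    _require_same_bins(ip, input_)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((ip.values > 0) & (input_.values > 0),
                         np.log2(ip.values / input_.values), np.nan)
    return BinnedTrack(ip.genome, ratio, "log2_ratio")


def zscore_per_chromosome(track: BinnedTrack) -> BinnedTrack:
    """Centre and scale values per chromosome over non-missing bins.

    A chromosome whose defined values are constant (SD = 0) or that has fewer
    than two defined bins becomes all-NaN.
    """
    _require_units(track, "log2_ratio", "cpm", "zscore", "log2_cpm1")
    out = np.full_like(track.values, np.nan)
    for chrom, (lo, hi) in track.genome.chrom_bounds().items():
        vals = track.values[lo:hi]
        ok = np.isfinite(vals)
        if ok.sum() < 2:
            continue
        sd = vals[ok].std()
        if sd == 0:
            continue
        out[lo:hi][ok] = (vals[ok] - vals[ok].mean()) / sd
    return BinnedTrack(track.genome, out, "zscore")


def smooth_nonzero(track: BinnedTrack, window: int = 3) -> BinnedTrack:
    """Smooth over non-zero bins only, the way sparse enrichment tracks are displayed.

    Per chromosome, the bins with defined non-zero values are taken in genomic
    order; each becomes the mean of itself and its ``(window-1)//2`` non-zero
    neighbours on each side (truncated at chromosome ends). Zero and missing
    bins pass through untouched, so the zero set is preserved.
    """
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    half = window // 2
    out = track.values.copy()
    for chrom, (lo, hi) in track.genome.chrom_bounds().items():
        vals = track.values[lo:hi]
        idx = np.flatnonzero(np.isfinite(vals) & (vals != 0))
        if idx.size == 0:
            continue
        v = vals[idx]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        k = np.arange(idx.size)
        a = np.maximum(k - half, 0)
        b = np.minimum(k + half, idx.size - 1)
        out[lo:hi][idx] = (csum[b + 1] - csum[a]) / (b - a + 1)
    return BinnedTrack(track.genome, out, track.units)


def rna_log_cpm(track: BinnedTrack, library_total: float | None = None) -> BinnedTrack:
    """RNA-seq display scale: log2(cpm + 1)."""
    cpm = cpm_normalize(track, library_total)
    return BinnedTrack(track.genome, np.log2(cpm.values + 1.0), "log2_cpm1")
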