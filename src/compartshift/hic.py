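"""Contact-map data model and Hi-C matrix operations.

The container stores one dense symmetric matrix per chromosome (cis only;
trans contacts are kept as a single total for QC ratios). Operations cover
blacklist masking, iterative-correction (ICE) balancing, distance-expected
profiles per chromosome arm, observed-over-expected maps, P(s) decay curves,
cis/trans QC counts and coarse differential (log-ratio) maps.

Balancing solves for per-bin weights ``w`` such that the corrected matrix
``c'_ij = c_ij * w_i * w_j`` has equal row sums over unmasked bins. One
update step divides each weight by its current relative marginal; run to
convergence (``tol`` mode) this is standard ICE, while ``n_iter=1`` applies a
single pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec, read_chrom_sizes

__all__ = [
    "ContactMap",
    "ExpectedProfile",
    "PsCurve",
    "load_matrix",
    "save_matrix",
    "apply_blacklist",
    "ice_normalize",
    "expected_cis",
    "observed_over_expected",
    "ps_curve",
    "cis_trans_ratio",
    "differential_map",
]


@dataclass
class ContactMap:
    """Binned symmetric cis contact matrices with mask and balancing weights.

    Attributes
    ----------
    genome
        Bin table provider; ``resolution`` is ``genome.bin_size``.
    matrices
        ``chrom -> (n, n)`` float array, symmetric. For ``kind='counts'``
        these are raw counts; for ``kind='oe'`` or ``kind='log2ratio'`` they
        are derived values with NaN marking undefined entries.
    mask
        Global boolean array, ``True`` for excluded bins.
    weights
        Per-bin balancing factors (NaN on masked bins), or ``None`` before
        balancing.
    trans_total
        Total trans contact count (kept only for QC).
    """

    genome: GenomeSpec
    matrices: dict[str, np.ndarray]
    mask: np.ndarray | None = None
    weights: np.ndarray | None = None
    trans_total: float = 0.0
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(self.genome.n_bins, dtype=bool)
        for chrom in self.genome.chrom_names:
            n = self.genome.n_bins_of(chrom)
            m = self.matrices[chrom]
            if m.shape != (n, n):
                raise ValueError(f"matrix for {chrom} has shape {m.shape}, expected {(n, n)}")

    @property
    def resolution(self) -> int:
        return self.genome.bin_size

    @classmethod
    def zeros(cls, genome: GenomeSpec, **kw) -> "ContactMap":
        mats = {c: np.zeros((genome.n_bins_of(c),) * 2) for c in genome.chrom_names}
        return cls(genome, mats, **kw)

    def copy(self) -> "ContactMap":
        return ContactMap(
            self.genome,
            {c: m.copy() for c, m in self.matrices.items()},
            self.mask.copy(),
            None if self.weights is None else self.weights.copy(),
            self.trans_total,
            self.kind,
        )

    def chrom_mask(self, chrom: str) -> np.ndarray:
        lo, hi = self.genome.chrom_bounds()[chrom]
        return self.mask[lo:hi]

    def balanced(self, chrom: str) -> np.ndarray:
        """Corrected matrix ``c * w_i * w_j`` with masked rows/columns NaN."""
        if self.weights is None:
            raise ValueError("map is not balanced; run ice_normalize first")
        lo, hi = self.genome.chrom_bounds()[chrom]
        w = self.weights[lo:hi]
        out = self.matrices[chrom] * np.outer(w, w)
        bad = self.chrom_mask(chrom)
        out[bad, :] = np.nan
        out[:, bad] = np.nan
        return out

    def total_cis(self) -> float:
        total = 0.0
        for chrom, m in self.matrices.items():
            total += np.triu(m).sum()
        return float(total)


@dataclass
class ExpectedProfile:
    """Per-arm expected contact value and valid-pair count at each bin distance."""

    arms: list[tuple[str, int, int]]
    values: list[np.ndarray]  # values[k][d] = E(d) for arm k, d >= 1
    counts: list[np.ndarray] = field(default_factory=list)

    def arm_for(self, chrom: str, bin_start: int) -> int | None:
        for k, (c, s, e) in enumerate(self.arms):
            if c == chrom and s <= bin_start < e:
                return k
        return None


@dataclass
class PsCurve:
    """Aggregated contact-frequency decay: mean balanced contact vs distance (bp)."""

    s: np.ndarray
    ps: np.ndarray

    def slope(self, s_min: float, s_max: float) -> float:
        """Log-log slope of the curve fitted on ``s_min <= s <= s_max``."""
        ok = (self.s >= s_min) & (self.s <= s_max) & (self.ps > 0)
        if ok.sum() < 2:
            raise ValueError("too few points in range for a slope fit")
        return float(np.polyfit(np.log10(self.s[ok]), np.log10(self.ps[ok]), 1)[0])


# ---------------------------------------------------------------------------
# I/O


def load_matrix(triplet_file, chrom_sizes, resolution: int) -> ContactMap:
    """Read a sparse triplet TSV (chrom, bin_i_start, bin_j_start, count).

    Duplicate (i, j) entries are summed; entries are mirrored so the stored
    matrix is symmetric. ``chrom_sizes`` may be a path to a two-column
    chrom.sizes file or a :class:`GenomeSpec`.
    """
    genome = (
        chrom_sizes
        if isinstance(chrom_sizes, GenomeSpec)
        else read_chrom_sizes(chrom_sizes, resolution)
    )
    if genome.bin_size != resolution:
        genome = genome.with_bin_size(resolution)
    cmap = ContactMap.zeros(genome)
    df = pd.read_csv(
        triplet_file, sep="\t", header=None,
        names=["chrom", "start_i", "start_j", "count"],
        dtype={"chrom": str}, comment="#",
    )
    if df.empty:
        return cmap
    sizes = genome.sizes
    for line_no, (chrom, si, sj, c) in enumerate(
        df.itertuples(index=False, name=None), start=1
    ):
        if chrom not in sizes:
            raise ValueError(f"line {line_no}: unknown chromosome {chrom!r}")
        if si % resolution or sj % resolution:
            raise ValueError(f"line {line_no}: coordinates not multiples of {resolution}")
        if not (0 <= si < sizes[chrom] and 0 <= sj < sizes[chrom]):
            raise ValueError(f"line {line_no}: coordinate outside chromosome {chrom!r}")
        i, j = si // resolution, sj // resolution
        m = cmap.matrices[chrom]
        m[i, j] += c
        if i != j:
            m[j, i] += c
    return cmap


def save_matrix(cmap: ContactMap, path, float_format: str = "%.10g") -> None:
    """Write the upper triangle (incl. diagonal) as a sparse triplet TSV."""
    res = cmap.resolution
    with open(path, "w") as fh:
        for chrom in cmap.genome.chrom_names:
            m = cmap.matrices[chrom]
            ii, jj = np.nonzero(np.triu(np.isfinite(m) & (m != 0)))
            for i, j in zip(ii, jj):
                fh.write(f"{chrom}\t{i * res}\t{j * res}\t{float_format % m[i, j]}\n")


# ---------------------------------------------------------------------------
# Masking and balancing


def apply_blacklist(cmap: ContactMap, regions: pd.DataFrame) -> ContactMap:
    """Mask every bin overlapping (>= 1 bp) a blacklist region; zero its rows/columns.

    ``regions`` needs ``chrom``, ``start``, ``end`` columns. Unknown
    chromosomes raise. Masking is idempotent.
    """
    out = cmap.copy()
    res = out.resolution
    bounds = out.genome.chrom_bounds()
    sizes = out.genome.sizes
    for chrom, start, end in regions[["chrom", "start", "end"]].itertuples(index=False):
        if chrom not in sizes:
            raise ValueError(f"blacklist names unknown chromosome {chrom!r}")
        start, end = max(0, int(start)), min(int(end), sizes[chrom])
        if end <= start:
            continue
        lo, _ = bounds[chrom]
        first = start // res
        last = (end - 1) // res
        out.mask[lo + first : lo + last + 1] = True
    for chrom in out.genome.chrom_names:
        bad = out.chrom_mask(chrom)
        out.matrices[chrom][bad, :] = 0.0
        out.matrices[chrom][:, bad] = 0.0
    if out.weights is not None:
        out.weights[out.mask] = np.nan
    return out


def ice_normalize(
    cmap: ContactMap,
    n_iter: int = 1,
    tol: float | None = None,
    max_iter: int = 1000,
) -> ContactMap:
    """Iterative-correction balancing, per chromosome.

    With ``tol`` set, updates run until the coefficient of variation of the
    unmasked corrected marginals drops below ``tol`` (or ``max_iter``);
    otherwise exactly ``n_iter`` update passes are applied (default one).
    Bins whose marginal is zero are added to the mask. Weights are
    normalised to mean 1 over unmasked bins of each chromosome.
    """
    out = cmap.copy()
    if out.mask.all():
        raise ValueError("all bins are masked; nothing to balance")
    weights = np.full(out.genome.n_bins, np.nan)
    for chrom in out.genome.chrom_names:
        lo, hi = out.genome.chrom_bounds()[chrom]
        m = out.matrices[chrom]
        bad = out.chrom_mask(chrom).copy()
        # zero-marginal bins can never be balanced
        marg0 = m.sum(axis=1)
        bad |= marg0 == 0
        if bad.all():
            out.mask[lo:hi] = True
            continue
        w = np.where(bad, 0.0, 1.0)
        iters = max_iter if tol is not None else n_iter
        for _ in range(iters):
            marg = w * (m @ w)
            mean = marg[~bad].mean()
            if tol is not None:
                cv = marg[~bad].std() / mean
                if cv < tol:
                    break
            delta = np.where(bad, 1.0, marg / mean)
            # guard: freshly-emptied bins
            delta[delta == 0] = 1.0
            w = w / delta
            w[~bad] /= w[~bad].mean()
        w[bad] = np.nan
        weights[lo:hi] = w
        out.mask[lo:hi] |= bad
    for chrom in out.genome.chrom_names:
        bad = out.chrom_mask(chrom)
        out.matrices[chrom][bad, :] = 0.0
        out.matrices[chrom][:, bad] = 0.0
    out.weights = weights
    return out


# ---------------------------------------------------------------------------
# Expected, O/E, P(s)


def _arm_bin_ranges(genome: GenomeSpec, arms=None):
    """Yield (chrom, lo, hi) global bin ranges for each arm."""
    arms = genome.arms() if arms is None else arms
    offsets = genome.chrom_offsets()
    res = genome.bin_size
    for chrom, start, end in arms:
        lo = offsets[chrom] + start // res
        hi = offsets[chrom] + -(-end // res)
        yield (chrom, start, end), lo, hi


def expected_cis(cmap: ContactMap, arms=None) -> ExpectedProfile:
    """Mean balanced contact at each bin distance, per chromosome arm.

    Masked bins are excluded from both numerator and denominator. Arms
    shorter than two bins are skipped with a warning. Without an arm list
    each chromosome is one arm.
    """
    arm_list, values, counts = [], [], []
    for arm, lo, hi in _arm_bin_ranges(cmap.genome, arms):
        n = hi - lo
        if n < 2:
            warnings.warn(f"arm {arm} shorter than 2 bins; skipped")
            continue
        chrom = arm[0]
        clo, _ = cmap.genome.chrom_bounds()[chrom]
        sub = cmap.balanced(chrom)[lo - clo : hi - clo, lo - clo : hi - clo]
        e = np.full(n, np.nan)
        c = np.zeros(n, dtype=np.int64)
        for d in range(1, n):
            diag = np.diagonal(sub, d)
            ok = np.isfinite(diag)
            c[d] = ok.sum()
            if c[d]:
                e[d] = diag[ok].mean()
        arm_list.append(arm)
        values.append(e)
        counts.append(c)
    return ExpectedProfile(arm_list, values, counts)


def observed_over_expected(cmap: ContactMap, expected: ExpectedProfile) -> ContactMap:
    """Balanced contact divided by the arm's expected at that distance.

    Entries are defined only within a single arm; cross-arm cis pairs, the
    diagonal, masked bins and distances with E(d) = 0 are NaN.
    """
    out = ContactMap(
        cmap.genome,
        {c: np.full(cmap.matrices[c].shape, np.nan) for c in cmap.genome.chrom_names},
        cmap.mask.copy(),
        None,
        cmap.trans_total,
        kind="oe",
    )
    bounds = cmap.genome.chrom_bounds()
    for k, (arm, lo, hi) in enumerate(_arm_bin_ranges(cmap.genome, expected.arms)):
        chrom = arm[0]
        clo, _ = bounds[chrom]
        a, b = lo - clo, hi - clo
        bal = cmap.balanced(chrom)[a:b, a:b]
        n = b - a
        e = expected.values[k]
        dist = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        emat = np.where(dist > 0, e[np.minimum(dist, n - 1)], np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(emat > 0, bal / emat, np.nan)
        out.matrices[chrom][a:b, a:b] = oe
    return out


def ps_curve(cmap: ContactMap, arms=None, points_per_decade: int = 8) -> PsCurve:
    """Contact-frequency decay P(s): per-arm expected aggregated genome-wide.

    Per-arm E(d) values are combined as a valid-pair-count weighted mean and
    smoothed into log-spaced distance bins (geometric mean distance per bin).
    """
    exp = expected_cis(cmap, arms)
    res = cmap.resolution
    max_d = max(len(v) for v in exp.values)
    num = np.zeros(max_d)
    den = np.zeros(max_d)
    for v, c in zip(exp.values, exp.counts):
        ok = np.isfinite(v)
        num[: len(v)][ok] += v[ok] * c[ok]
        den[: len(v)][ok] += c[ok]
    d = np.arange(1, max_d)
    mean = np.where(den[1:] > 0, num[1:] / np.maximum(den[1:], 1), np.nan)
    # log-spaced aggregation
    edges = np.unique(
        np.round(10 ** np.arange(0, np.log10(max_d) + 1.0 / points_per_decade,
                                 1.0 / points_per_decade)).astype(int)
    )
    s_out, p_out = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        sel = (d >= a) & (d < b) & np.isfinite(mean) & (den[1:][d - 1] > 0)
        if not sel.any():
            continue
        w = den[1:][d[sel] - 1]
        s_out.append(np.exp(np.average(np.log(d[sel] * res), weights=w)))
        p_out.append(np.average(mean[sel], weights=w))
    return PsCurve(np.asarray(s_out), np.asarray(p_out))


# ---------------------------------------------------------------------------
# QC and differential maps


def cis_trans_ratio(cmap: ContactMap, threshold: int = 20_000) -> dict:
    """Short-range (<= threshold between bin starts), long-range cis and trans totals.

    The threshold is inclusive. Returns raw totals and the cis/trans ratio
    (``inf`` when no trans contacts are recorded, flagged ``undefined``).
    """
    res = cmap.resolution
    short = long_ = 0.0
    dmax = threshold // res
    for chrom in cmap.genome.chrom_names:
        m = cmap.matrices[chrom]
        n = m.shape[0]
        for d in range(0, n):
            tot = np.diagonal(m, d).sum()
            if d <= dmax:
                short += tot
            else:
                long_ += tot
    trans = float(cmap.trans_total)
    cis = short + long_
    ratio = np.inf if trans == 0 else cis / trans
    return {
        "short_cis": float(short),
        "long_cis": float(long_),
        "trans": trans,
        "cis_trans_ratio": float(ratio),
        "undefined": trans == 0,
    }


def _coarsen_balanced(cmap: ContactMap, target: int):
    """Sum balanced values into coarse bins; cells with no valid pairs are NaN."""
    factor = target // cmap.resolution
    if target % cmap.resolution:
        raise ValueError("target resolution must be a multiple of the map resolution")
    coarse = cmap.genome.with_bin_size(target)
    out = {}
    for chrom in cmap.genome.chrom_names:
        bal = cmap.balanced(chrom)
        n = bal.shape[0]
        nc = coarse.n_bins_of(chrom)
        pad = nc * factor - n
        if pad:
            bal = np.pad(bal, ((0, pad), (0, pad)), constant_values=np.nan)
        blocks = bal.reshape(nc, factor, nc, factor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            summed = np.nansum(blocks, axis=(1, 3))
            valid = np.isfinite(blocks).sum(axis=(1, 3))
        out[chrom] = np.where(valid > 0, summed, np.nan)
    return coarse, out


def differential_map(map_a: ContactMap, map_b: ContactMap, resolution: int = 1_000_000) -> ContactMap:
    """Per-entry log2(B/A) of balanced contacts coarsened to ``resolution``.

    Both maps must be balanced and share a bin table. Entries where either
    coarse cell is zero or undefined are NaN. Swapping the arguments negates
    the result.
    """
    if map_a.genome != map_b.genome:
        raise ValueError("maps have mismatched bin tables")
    coarse, ca = _coarsen_balanced(map_a, resolution)
    _, cb = _coarsen_balanced(map_b, resolution)
    mats = {}
    for chrom in coarse.chrom_names:
        a, b = ca[chrom], cb[chrom]
        with np.errstate(divide="ignore", invalid="ignore"):
            mats[chrom] = np.where((a > 0) & (b > 0), np.log2(b / a), np.nan)
    return ContactMap(coarse, mats, kind="log2ratio")
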