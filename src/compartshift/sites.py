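"""Site-level analyses of genomic interval sets.

This module handles interval sets such as the early-replication initiation
zone classes ("blurred": transcribed regions whose H3.3/replication
boundaries lose precision, "buried": non/low-transcribed peaks that lose
early firing): signal stack-ups and mean profiles, per-site mean EV1,
quadrant switching classification between two conditions, size- (and
optionally compartment-) matched randomised controls, expression summaries,
group comparisons with rank tests, and interval intersection utilities.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compartments import CompartmentTrack
from .genome import GenomeSpec
from .stats import bh_fdr, mann_whitney_u, star_code
from .tracks import BinnedTrack

__all__ = [
    "SiteSet",
    "QuadrantResult",
    "stackup",
    "mean_profile",
    "site_mean_ev1",
    "quadrant_classify",
    "cross_line_quadrants",
    "randomize_sites",
    "site_expression",
    "rescue_group_compare",
    "common_intervals",
]


@dataclass
class SiteSet:
    """Genomic intervals of one class with optional per-site summary columns.

    ``intervals`` holds ``chrom, start, end, id`` (0-based half-open, unique
    ids); extra columns (mean EV1 per condition, expression, ...) may be
    attached by the analysis functions. ``site_class`` is one of ``blurred``,
    ``buried``, ``random``, ``peak``.
    """

    intervals: pd.DataFrame
    site_class: str = "peak"

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True).copy()
        if "id" not in df.columns:
            df["id"] = [f"{self.site_class}_{i}" for i in range(len(df))]
        if (df["start"] >= df["end"]).any():
            raise ValueError("intervals must have start < end")
        if df["id"].duplicated().any():
            raise ValueError("site ids must be unique")
        self.intervals = df

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def sizes(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()

    def to_bed(self, path) -> None:
        df = self.intervals[["chrom", "start", "end", "id"]].copy()
        df["class"] = self.site_class
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path, site_class: str | None = None) -> "SiteSet":
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         names=["chrom", "start", "end", "id", "class"],
                         dtype={"chrom": str}, usecols=range(5))
        cls_name = site_class or (df["class"].iloc[0] if len(df) else "peak")
        return cls(df[["chrom", "start", "end", "id"]], cls_name)


# ---------------------------------------------------------------------------
# Stack-ups and profiles


def _stack_intervals(track: BinnedTrack, intervals: pd.DataFrame, flank: int) -> np.ndarray:
    """One row per interval: track values around the midpoint bin, ±flank."""
    res = track.resolution
    if flank % res:
        raise ValueError("flank must be a multiple of the track resolution")
    half = flank // res
    width = 2 * half + 1
    bounds = track.genome.chrom_bounds()
    out = np.full((len(intervals), width), np.nan)
    for row, (chrom, start, end) in enumerate(
        intervals[["chrom", "start", "end"]].itertuples(index=False)
    ):
        if chrom not in bounds:
            warnings.warn(f"site on unknown chromosome {chrom!r} skipped")
            continue
        lo, hi = bounds[chrom]
        mid_bin = ((start + end) // 2) // res  # midpoint snapped to its bin
        a = mid_bin - half
        b = mid_bin + half + 1
        src_a, src_b = max(a, 0), min(b, hi - lo)
        if src_a >= src_b:
            continue
        out[row, src_a - a : src_b - a] = track.values[lo + src_a : lo + src_b]
    return out


def stackup(track: BinnedTrack, sites: SiteSet, flank: int = 500_000,
            sort: str = "size_desc"):
    """Site-centred signal matrix, rows ordered by site size.

    Returns ``(matrix, ordered_sites)``; each row spans ±flank around the
    site midpoint at the track resolution, NaN outside the chromosome.
    """
    df = sites.intervals.copy()
    df["size"] = df["end"] - df["start"]
    if sort == "size_desc":
        df = df.sort_values("size", ascending=False, kind="stable")
    elif sort == "size_asc":
        df = df.sort_values("size", ascending=True, kind="stable")
    elif sort is not None and sort != "none":
        raise ValueError(f"unknown sort {sort!r}")
    df = df.reset_index(drop=True)
    return _stack_intervals(track, df, flank), df


def mean_profile(stack: np.ndarray, sites: pd.DataFrame,
                 size_window: tuple[int, int] | None = (60_000, 160_000)) -> np.ndarray:
    """Column-wise mean over rows whose site size lies in ``size_window``.

    ``sites`` is the ordered table returned by :func:`stackup` (needs a
    ``size`` column). Missing cells are ignored; an empty selection returns
    an empty array with a warning.
    """
    sizes = (sites["end"] - sites["start"]).to_numpy() if "size" not in sites else sites["size"].to_numpy()
    keep = np.ones(len(sites), dtype=bool)
    if size_window is not None:
        keep = (sizes >= size_window[0]) & (sizes <= size_window[1])
    if not keep.any():
        warnings.warn("no sites in the requested size window")
        return np.empty(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(stack[keep], axis=0)


# ---------------------------------------------------------------------------
# EV1 at sites and quadrant classification


def site_mean_ev1(ev: CompartmentTrack, sites: SiteSet, fine_resolution: int = 10_000,
                  min_defined_frac: float = 0.5) -> np.ndarray:
    """Mean EV1 per site after piecewise-constant re-binning to ``fine_resolution``.

    Each fine bin inherits its parent coarse-bin EV1 value; a site's value is
    the mean over its overlapping fine bins with defined EV1. Sites where
    fewer than ``min_defined_frac`` of overlapping bins are defined get NaN.
    """
    res = ev.genome.bin_size
    out = np.full(len(sites), np.nan)
    bounds = ev.genome.chrom_bounds()
    sizes = ev.genome.sizes
    for k, (chrom, start, end) in enumerate(
        sites.intervals[["chrom", "start", "end"]].itertuples(index=False)
    ):
        if chrom not in bounds:
            continue
        lo, _ = bounds[chrom]
        start_c = max(0, start)
        end_c = min(end, sizes[chrom])
        if end_c <= start_c:
            continue
        fine_starts = np.arange(
            (start_c // fine_resolution) * fine_resolution, end_c, fine_resolution
        )
        vals = ev.ev1[lo + fine_starts // res]
        ok = np.isfinite(vals)
        if ok.sum() == 0 or ok.mean() < min_defined_frac:
            continue
        out[k] = vals[ok].mean()
    return out


@dataclass
class QuadrantResult:
    """Per-site compartment-switch quadrant labels and proportions."""

    labels: np.ndarray  # 'A-to-B' | 'B-to-A' | 'A-stable' | 'B-stable' | 'NA'
    proportions: dict[str, float] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {k: 0 for k in ("A-to-B", "B-to-A", "A-stable", "B-stable", "NA")}
        lab, cnt = np.unique(self.labels, return_counts=True)
        out.update(dict(zip(lab, cnt.astype(int))))
        return out


def quadrant_classify(mean_ev_cond1, mean_ev_cond2) -> QuadrantResult:
    """Classify sites by the sign of their mean EV1 in two conditions.

    (+, -) is A-to-B (lower-right quadrant of a cond1-vs-cond2 scatter),
    (-, +) is B-to-A (upper-left), (+, +) A-stable, (-, -) B-stable; a zero
    or undefined value in either condition gives NA. Proportions are over
    non-NA sites.
    """
    e1 = np.asarray(mean_ev_cond1, dtype=float)
    e2 = np.asarray(mean_ev_cond2, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError("per-site value vectors are not paired")
    labels = np.full(e1.shape, "NA", dtype=object)
    ok = np.isfinite(e1) & np.isfinite(e2) & (e1 != 0) & (e2 != 0)
    labels[ok & (e1 > 0) & (e2 < 0)] = "A-to-B"
    labels[ok & (e1 < 0) & (e2 > 0)] = "B-to-A"
    labels[ok & (e1 > 0) & (e2 > 0)] = "A-stable"
    labels[ok & (e1 < 0) & (e2 < 0)] = "B-stable"
    n = int(ok.sum())
    props = {}
    if n:
        for key in ("A-to-B", "B-to-A", "A-stable", "B-stable"):
            props[key] = float((labels == key).sum() / n)
        props["switching"] = props["A-to-B"] + props["B-to-A"]
    return QuadrantResult(labels, props)


def cross_line_quadrants(per_line_pairs) -> pd.DataFrame:
    """Summarise quadrant proportions as mean ± SD across replicate cell lines.

    ``per_line_pairs`` is a sequence of ``(mean_ev_cond1, mean_ev_cond2)``
    pairs, one per cell line. Returns a table with one row per category.
    """
    results = [quadrant_classify(a, b) for a, b in per_line_pairs]
    keys = ("A-to-B", "B-to-A", "A-stable", "B-stable", "switching")
    rows = []
    for key in keys:
        vals = np.array([r.proportions.get(key, np.nan) for r in results])
        rows.append((key, float(np.nanmean(vals)), float(np.nanstd(vals))))
    return pd.DataFrame(rows, columns=["category", "mean", "sd"])


# ---------------------------------------------------------------------------
# Randomised controls


def _site_compartment_labels(sites: SiteSet, ev: CompartmentTrack) -> np.ndarray:
    mean_ev = site_mean_ev1(ev, sites)
    lab = np.full(len(sites), "NA", dtype=object)
    lab[np.isfinite(mean_ev) & (mean_ev > 0)] = "A"
    lab[np.isfinite(mean_ev) & (mean_ev < 0)] = "B"
    return lab


def randomize_sites(
    sites: SiteSet,
    genome: GenomeSpec,
    mask: np.ndarray | None = None,
    seed: int = 0,
    match_compartment: CompartmentTrack | None = None,
    max_tries: int = 2000,
) -> SiteSet:
    """Random control sites with the exact length multiset of the input.

    Placement is uniform over the genome (proportional to chromosome length),
    rejecting positions that overlap a masked bin (``mask`` is a per-bin
    boolean on ``genome``'s bin table) or a previously placed site. With
    ``match_compartment``, placements are additionally rejected until the
    random set's A/B/NA label counts (by mean EV1 sign) equal those of the
    input set.
    """
    rng = np.random.default_rng(seed)
    lengths = sorted(sites.sizes.tolist(), reverse=True)  # big ones first: easier packing
    chroms = genome.chrom_names
    csizes = np.array([genome.sizes[c] for c in chroms], dtype=float)
    probs = csizes / csizes.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    need: dict[str, int] | None = None
    if match_compartment is not None:
        lab, cnt = np.unique(_site_compartment_labels(sites, match_compartment),
                             return_counts=True)
        need = dict(zip(lab, cnt.astype(int)))
    res = genome.bin_size

    def overlaps_mask(chrom: str, start: int, end: int) -> bool:
        if mask is None:
            return False
        lo, _ = genome.chrom_bounds()[chrom]
        return bool(mask[lo + start // res : lo + (end - 1) // res + 1].any())

    def overlaps_placed(chrom: str, start: int, end: int) -> bool:
        ivs = placed[chrom]
        i = bisect.bisect_left(ivs, (start, end))
        if i < len(ivs) and ivs[i][0] < end:
            return True
        if i > 0 and ivs[i - 1][1] > start:
            return True
        return False

    rows = []
    for k, length in enumerate(lengths):
        for attempt in range(max_tries):
            ci = rng.choice(len(chroms), p=probs)
            chrom = chroms[ci]
            limit = genome.sizes[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            if overlaps_mask(chrom, start, end) or overlaps_placed(chrom, start, end):
                continue
            if need is not None:
                candidate = SiteSet(
                    pd.DataFrame({"chrom": [chrom], "start": [start], "end": [end]}),
                    "random",
                )
                lab = _site_compartment_labels(candidate, match_compartment)[0]
                if need.get(lab, 0) <= 0:
                    continue
                need[lab] -= 1
            bisect.insort(placed[chrom], (start, end))
            rows.append((chrom, start, end, f"random_{k}"))
            break
        else:
            raise RuntimeError(
                f"could not place a random site of length {length} "
                f"after {max_tries} tries"
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    return SiteSet(df.sort_values(["chrom", "start"], kind="stable"), "random")


# ---------------------------------------------------------------------------
# Expression and group comparisons


def site_expression(rna: BinnedTrack, sites: SiteSet) -> np.ndarray:
    """Mean RNA signal (log2(cpm+1)) over each site's overlapping bins."""
    res = rna.resolution
    bounds = rna.genome.chrom_bounds()
    sizes = rna.genome.sizes
    out = np.full(len(sites), np.nan)
    for k, (chrom, start, end) in enumerate(
        sites.intervals[["chrom", "start", "end"]].itertuples(index=False)
    ):
        if chrom not in bounds:
            continue
        lo, _ = bounds[chrom]
        a = max(0, start) // res
        b = (min(end, sizes[chrom]) - 1) // res + 1
        vals = rna.values[lo + a : lo + b]
        ok = np.isfinite(vals)
        if ok.any():
            out[k] = vals[ok].mean()
    return out


def rescue_group_compare(group_labels, values_by_condition: dict) -> pd.DataFrame:
    """Compare per-site signal between label groups and between conditions.

    ``group_labels`` assigns each site to a group (e.g. 'B-to-A' vs
    'B-stable' from :func:`quadrant_classify`); ``values_by_condition`` maps
    condition name to a per-site value vector. For every condition the two
    largest groups are compared, and within every group all condition pairs
    are compared, with two-tailed Mann-Whitney U tests corrected jointly by
    Benjamini-Hochberg. Groups with fewer than two defined values are
    skipped and flagged.
    """
    labels = np.asarray(group_labels, dtype=object)
    groups = [g for g in pd.unique(labels) if g != "NA"]
    comparisons, rows = [], []

    def grab(g, cond):
        v = np.asarray(values_by_condition[cond], dtype=float)[labels == g]
        return v[np.isfinite(v)]

    for cond in values_by_condition:
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                comparisons.append((f"{groups[i]}-vs-{groups[j]}@{cond}",
                                    grab(groups[i], cond), grab(groups[j], cond)))
    conds = list(values_by_condition)
    for g in groups:
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                comparisons.append((f"{conds[i]}-vs-{conds[j]}@{g}",
                                    grab(g, conds[i]), grab(g, conds[j])))
    for name, a, b in comparisons:
        if a.size < 2 or b.size < 2:
            rows.append((name, a.size, b.size, np.nan, np.nan, "skipped"))
            continue
        res = mann_whitney_u(a, b)
        rows.append((name, a.size, b.size, res.u, res.p, "tested"))
    df = pd.DataFrame(rows, columns=["comparison", "n1", "n2", "U", "p", "status"])
    tested = df["status"] == "tested"
    q = np.full(len(df), np.nan)
    if tested.any():
        q[tested] = bh_fdr(df.loc[tested, "p"].to_numpy())
    df["q"] = q
    df["stars"] = [star_code(v) if np.isfinite(v) else "" for v in q]
    return df


# ---------------------------------------------------------------------------
# Interval utilities


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def common_intervals(*site_sets: SiteSet) -> SiteSet:
    """Regions covered by every input set (>= 1 bp overlap), as overlap regions."""
    if not site_sets:
        raise ValueError("need at least one site set")
    per_chrom: dict[str, list[tuple[int, int]]] | None = None
    for ss in site_sets:
        cur: dict[str, list[tuple[int, int]]] = {}
        for chrom, sub in ss.intervals.groupby("chrom"):
            cur[chrom] = _merge(list(zip(sub["start"], sub["end"])))
        if per_chrom is None:
            per_chrom = cur
            continue
        nxt: dict[str, list[tuple[int, int]]] = {}
        for chrom in per_chrom.keys() & cur.keys():
            a, b = per_chrom[chrom], cur[chrom]
            i = j = 0
            acc = []
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    acc.append((s, e))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
            if acc:
                nxt[chrom] = acc
        per_chrom = nxt
    rows = [
        (chrom, s, e)
        for chrom in sorted(per_chrom or {})
        for s, e in per_chrom[chrom]
    ]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return SiteSet(df, "peak")
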