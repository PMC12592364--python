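"""Synthetic Hi-C maps, coverage tracks and site sets with planted truth.

The generative model plants two-state (A/B) compartment identity in
alternating blocks with geometric lengths, then draws cis contact counts as

    c_ij ~ Poisson(C * |i - j|^(-alpha) * exp(kappa * s_i * s_j)),  i != j,

where ``s`` is the planted sign and ``C`` scales the expected total cis count
to the requested sequencing depth. A condition-2 profile flips a Bernoulli
fraction of bins, either concordantly across two replicate "cell lines" or
independently; decoy flips confined to one line exercise the concordance
rule of the switching classifier. TAD maps multiply within-block contacts by
a boost factor before sampling. IP/input track pairs draw Poisson counts
whose IP rate is raised by exp(beta) inside A bins and/or around site
boundaries. Every generator is a pure function of its arguments including
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .genome import GenomeSpec
from .hic import ContactMap
from .sites import SiteSet
from .tracks import BinnedTrack

__all__ = [
    "PlantedTruth",
    "SimParams",
    "generate_compartment_profile",
    "simulate_hic",
    "simulate_tads",
    "simulate_track",
    "generate_sites",
    "gc_track",
    "write_truth",
    "read_truth",
]


@dataclass
class SimParams:
    """Generative parameters for synthetic Hi-C and coverage tracks.

    decay_exponent
        Power-law exponent alpha of contact decay with bin distance (> 0).
    compartment_strength
        kappa >= 0; same-sign contacts are boosted by exp(2*kappa) relative
        to opposite-sign at equal distance.
    sequencing_depth
        Expected total cis contact count over the genome (> 0).
    ip_effect
        beta, log-scale IP enrichment over input where the planted indicator
        is 1.
    dispersion
        Optional negative-binomial size parameter; ``None`` keeps pure
        Poisson noise.
    trans_over_cis
        Expected trans contacts as a fraction of cis (uniform background,
        kept only for the cis/trans QC ratio).
    """

    decay_exponent: float = 1.0
    compartment_strength: float = 0.4
    sequencing_depth: float = 1e6
    ip_effect: float = 1.0
    dispersion: float | None = None
    trans_over_cis: float = 1.0 / 9.0

    def __post_init__(self) -> None:
        for name in ("decay_exponent", "compartment_strength", "sequencing_depth",
                     "ip_effect", "trans_over_cis"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.compartment_strength < 0:
            raise ValueError("compartment_strength must be >= 0")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be > 0")


@dataclass
class PlantedTruth:
    """Ground truth of a simulated experiment.

    ``signs`` has shape ``(n_lines, 2 conditions, n_bins)`` with values ±1.
    ``switch_bins`` are the bins planted to flip sign concordantly in all
    lines between condition 1 and 2; ``decoy_bins`` flipped in a single line
    only. ``tad_boundaries`` are global bin indices on the bin grid they
    were generated at.
    """

    genome: GenomeSpec
    signs: np.ndarray
    switch_bins: np.ndarray
    decoy_bins: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    tad_boundaries: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    seed: int = 0

    @property
    def n_lines(self) -> int:
        return self.signs.shape[0]

    def sign(self, line: int = 0, condition: int = 0) -> np.ndarray:
        return self.signs[line, condition]


def _geometric_blocks(n_bins: int, mean_len: float, rng: np.random.Generator) -> np.ndarray:
    """Alternating ±1 blocks with geometric lengths of the given mean."""
    signs = np.empty(n_bins, dtype=np.int8)
    cur = 1 if rng.random() < 0.5 else -1
    i = 0
    p = 1.0 / mean_len
    while i < n_bins:
        length = rng.geometric(p)
        signs[i : i + length] = cur
        cur = -cur
        i += length
    return signs


def generate_compartment_profile(
    genome: GenomeSpec,
    mean_block_len: int = 1_000_000,
    switch_fraction: float = 0.05,
    concordant: bool = True,
    decoy_fraction: float = 0.0,
    n_lines: int = 2,
    seed: int = 0,
) -> PlantedTruth:
    """Plant compartment signs per bin for two conditions and replicate lines.

    Block lengths are geometric with mean ``mean_block_len`` (bp, must be at
    least two bins). Each bin flips sign in condition 2 with probability
    ``switch_fraction`` (in [0, 0.5]): identically across lines when
    ``concordant``, independently per line otherwise. ``decoy_fraction``
    plants additional flips in the *last* line only (discordant decoys).
    """
    if not 0 <= switch_fraction <= 0.5:
        raise ValueError("switch_fraction must lie in [0, 0.5]")
    if not 0 <= decoy_fraction <= 0.5:
        raise ValueError("decoy_fraction must lie in [0, 0.5]")
    mean_bins = mean_block_len / genome.bin_size
    if mean_bins < 2:
        raise ValueError("mean_block_len must be at least two bins")
    rng = np.random.default_rng(seed)
    n = genome.n_bins
    base = np.empty(n, dtype=np.int8)
    for chrom, (lo, hi) in genome.chrom_bounds().items():
        base[lo:hi] = _geometric_blocks(hi - lo, mean_bins, rng)
    signs = np.empty((n_lines, 2, n), dtype=np.int8)
    signs[:, 0, :] = base
    if concordant:
        flips = rng.random(n) < switch_fraction
        switch_bins = np.flatnonzero(flips)
        for line in range(n_lines):
            signs[line, 1] = np.where(flips, -base, base)
    else:
        per_line = rng.random((n_lines, n)) < switch_fraction
        for line in range(n_lines):
            signs[line, 1] = np.where(per_line[line], -base, base)
        switch_bins = np.flatnonzero(per_line.all(axis=0))
    decoy_bins = np.empty(0, dtype=np.int64)
    if decoy_fraction > 0 and n_lines > 1:
        already = signs[0, 1] != signs[0, 0]
        candidates = rng.random(n) < decoy_fraction
        decoy = candidates & ~already & (signs[-1, 1] == signs[-1, 0])
        decoy_bins = np.flatnonzero(decoy)
        signs[-1, 1, decoy_bins] = -signs[-1, 1, decoy_bins]
    return PlantedTruth(genome, signs, switch_bins.astype(np.int64), decoy_bins, seed=seed)


def _sample_counts(expected: np.ndarray, rng: np.random.Generator,
                   dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(expected).astype(float)
    # gamma-Poisson mixture: NB with size r, mean = expected
    lam = rng.gamma(dispersion, expected / dispersion)
    return rng.poisson(lam).astype(float)


def _finalize_map(genome: GenomeSpec, mats: dict, params: SimParams,
                  rng: np.random.Generator) -> ContactMap:
    trans = float(rng.poisson(params.sequencing_depth * params.trans_over_cis))
    cmap = ContactMap(genome, mats, trans_total=trans)
    empty = 0
    for chrom in genome.chrom_names:
        empty += int((mats[chrom].sum(axis=1) == 0).sum())
    if empty > 0.5 * genome.n_bins:
        warnings.warn("over half of the bins have no contacts; depth may be too low")
    return cmap


def simulate_hic(
    truth: PlantedTruth,
    params: SimParams,
    seed: int = 0,
    line: int = 0,
    condition: int = 0,
) -> ContactMap:
    """Draw a cis contact map for one (line, condition) of a planted truth.

    Expected counts follow ``C * d^(-alpha) * exp(kappa * s_i * s_j)`` off
    the diagonal; ``C`` scales the genome total to ``sequencing_depth``,
    split across chromosomes in proportion to their unscaled totals.
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome
    s = truth.sign(line, condition).astype(float)
    shapes = {}
    total_weight = 0.0
    for chrom, (lo, hi) in genome.chrom_bounds().items():
        n = hi - lo
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        with np.errstate(divide="ignore"):
            decay = np.where(d > 0, d**-params.decay_exponent, 0.0)
        mod = np.exp(params.compartment_strength * np.outer(s[lo:hi], s[lo:hi]))
        e = decay * mod
        shapes[chrom] = e
        total_weight += np.triu(e, 1).sum()
    scale = params.sequencing_depth / total_weight
    mats = {}
    for chrom, e in shapes.items():
        n = e.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        counts = _sample_counts(e[iu, ju] * scale, rng, params.dispersion)
        m = np.zeros((n, n))
        m[iu, ju] = counts
        m += m.T
        mats[chrom] = m
    return _finalize_map(genome, mats, params, rng)


def simulate_tads(
    genome: GenomeSpec,
    boundary_spacing: int,
    inside_boost: float,
    params: SimParams,
    seed: int = 0,
):
    """Contact map with planted TAD blocks of fixed spacing.

    Within-block expected contacts are multiplied by ``inside_boost`` (>= 1)
    before Poisson sampling. Returns ``(ContactMap, boundaries)`` where
    boundaries are global bin indices of interior block starts.
    """
    if inside_boost < 1:
        raise ValueError("inside_boost must be >= 1")
    rng = np.random.default_rng(seed)
    shapes = {}
    boundaries = []
    total_weight = 0.0
    res = genome.bin_size
    for chrom, (lo, hi) in genome.chrom_bounds().items():
        n = hi - lo
        block = (np.arange(n) * res) // boundary_spacing
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).astype(float)
        with np.errstate(divide="ignore"):
            decay = np.where(d > 0, d**-params.decay_exponent, 0.0)
        same = block[:, None] == block[None, :]
        e = decay * np.where(same, inside_boost, 1.0)
        shapes[chrom] = e
        total_weight += np.triu(e, 1).sum()
        change = np.flatnonzero(np.diff(block) != 0) + 1
        boundaries.extend((lo + change).tolist())
    scale = params.sequencing_depth / total_weight
    mats = {}
    for chrom, e in shapes.items():
        n = e.shape[0]
        iu, ju = np.triu_indices(n, k=1)
        counts = _sample_counts(e[iu, ju] * scale, rng, params.dispersion)
        m = np.zeros((n, n))
        m[iu, ju] = counts
        m += m.T
        mats[chrom] = m
    return _finalize_map(genome, mats, params, rng), np.asarray(boundaries, dtype=np.int64)


def simulate_track(
    truth: PlantedTruth,
    sites: SiteSet | None,
    params: SimParams,
    seed: int = 0,
    resolution: int = 10_000,
    boundary_flank: int = 20_000,
    line: int = 0,
    condition: int = 0,
    compartment_effect: bool = True,
) -> tuple[BinnedTrack, BinnedTrack]:
    """Draw an (IP, input) count-track pair at ``resolution``.

    Input counts are Poisson with a flat rate summing to ``sequencing_depth``;
    IP counts multiply that rate by ``exp(ip_effect)`` wherever the planted
    indicator is 1: in A bins (when ``compartment_effect``) and within
    ±``boundary_flank`` of each site edge.
    """
    rng = np.random.default_rng(seed)
    fine = truth.genome.with_bin_size(resolution)
    factor = truth.genome.bin_size // resolution
    if truth.genome.bin_size % resolution:
        raise ValueError("track resolution must divide the truth bin size")
    f = np.zeros(fine.n_bins)
    if compartment_effect:
        s = truth.sign(line, condition)
        bounds = truth.genome.chrom_bounds()
        fbounds = fine.chrom_bounds()
        for chrom in truth.genome.chrom_names:
            lo, hi = bounds[chrom]
            flo, fhi = fbounds[chrom]
            rep = np.repeat(s[lo:hi] > 0, factor)[: fhi - flo]
            f[flo:fhi] = np.where(rep, 1.0, f[flo:fhi])
    if sites is not None:
        fb = fine.chrom_bounds()
        sizes = fine.sizes
        for chrom, start, end in sites.intervals[["chrom", "start", "end"]].itertuples(index=False):
            if chrom not in fb:
                raise ValueError(f"site outside genome: {chrom!r}")
            flo, fhi = fb[chrom]
            for edge in (start, end):
                a = max(0, edge - boundary_flank) // resolution
                b = (min(sizes[chrom], edge + boundary_flank) - 1) // resolution + 1
                f[flo + a : min(flo + b, fhi)] = 1.0
    lam = params.sequencing_depth / fine.n_bins
    input_counts = rng.poisson(lam, size=fine.n_bins).astype(float)
    ip_counts = rng.poisson(lam * np.exp(params.ip_effect * f)).astype(float)
    return (BinnedTrack(fine, ip_counts, "counts"),
            BinnedTrack(fine, input_counts, "counts"))


def generate_sites(
    genome: GenomeSpec,
    n: int,
    size_range: tuple[int, int] = (20_000, 300_000),
    seed: int = 0,
    max_tries: int = 200,
) -> SiteSet:
    """n non-overlapping intervals with log-uniform sizes in ``size_range``."""
    lo_s, hi_s = size_range
    if not 0 < lo_s <= hi_s:
        raise ValueError("invalid size_range")
    if n * hi_s >= sum(genome.sizes.values()):
        raise ValueError("requested sites cannot fit in the genome")
    rng = np.random.default_rng(seed)
    sizes = np.exp(rng.uniform(np.log(lo_s), np.log(hi_s), size=n)).astype(np.int64)
    sizes = np.clip(sizes, lo_s, hi_s)
    chroms = genome.chrom_names
    csizes = np.array([genome.sizes[c] for c in chroms], dtype=float)
    probs = csizes / csizes.sum()
    import bisect as _bisect

    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for k in np.argsort(sizes)[::-1]:  # place large sites first
        length = int(sizes[k])
        for _ in range(max_tries):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            limit = genome.sizes[chrom] - length
            if limit <= 0:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            ivs = placed[chrom]
            i = _bisect.bisect_left(ivs, (start, end))
            if (i < len(ivs) and ivs[i][0] < end) or (i > 0 and ivs[i - 1][1] > start):
                continue
            _bisect.insort(ivs, (start, end))
            rows.append((chrom, start, end, f"site_{k}"))
            break
        else:
            raise RuntimeError(f"failed to place site of length {length}")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    df = df.sort_values(["chrom", "start"], kind="stable")
    return SiteSet(df, "peak")


def gc_track(
    truth: PlantedTruth,
    seed: int = 0,
    base: float = 0.40,
    a_shift: float = 0.05,
    noise_sd: float = 0.005,
    line: int = 0,
    condition: int = 0,
) -> BinnedTrack:
    """Synthetic GC-content track correlated with the planted A identity.

    Real A compartments are GC-rich; the generated track is ``base +
    a_shift`` in planted A bins plus Gaussian noise, which is what the EV1
    sign-orientation step needs.
    """
    rng = np.random.default_rng(seed)
    s = truth.sign(line, condition)
    vals = base + a_shift * (s > 0) + rng.normal(0, noise_sd, size=s.size)
    return BinnedTrack(truth.genome, vals, "gc")


# ---------------------------------------------------------------------------
# Truth serialization (test oracles need file-level access)


def write_truth(truth: PlantedTruth, path) -> None:
    df = truth.genome.bin_table()
    for line in range(truth.n_lines):
        for cond in range(2):
            df[f"sign_line{line + 1}_cond{cond + 1}"] = truth.signs[line, cond]
    flags = np.zeros(truth.genome.n_bins, dtype=int)
    flags[truth.switch_bins] = 1
    df["is_switch"] = flags
    decoy = np.zeros(truth.genome.n_bins, dtype=int)
    decoy[truth.decoy_bins] = 1
    df["is_decoy"] = decoy
    df["is_tad_boundary"] = 0
    df.loc[df.index.isin(truth.tad_boundaries), "is_tad_boundary"] = 1
    df.to_csv(path, sep="\t", index=False)


def read_truth(path, genome: GenomeSpec | None = None) -> PlantedTruth:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if genome is None:
        sizes = df.groupby("chrom", sort=False)["end"].max()
        bin_size = int((df["end"] - df["start"]).max())
        genome = GenomeSpec(tuple(sizes.items()), bin_size)
    sign_cols = sorted(c for c in df.columns if c.startswith("sign_line"))
    n_lines = len(sign_cols) // 2
    signs = np.empty((n_lines, 2, len(df)), dtype=np.int8)
    for line in range(n_lines):
        for cond in range(2):
            signs[line, cond] = df[f"sign_line{line + 1}_cond{cond + 1}"]
    return PlantedTruth(
        genome,
        signs,
        np.flatnonzero(df["is_switch"].to_numpy()),
        np.flatnonzero(df["is_decoy"].to_numpy()),
        np.flatnonzero(df["is_tad_boundary"].to_numpy()),
    )
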