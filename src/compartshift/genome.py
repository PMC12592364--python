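"""Genome model: chromosome sizes, bin tables and chromosome arms.

All coordinates are 0-based half-open (BED convention). A genome is binned at
a fixed resolution; the last bin of each chromosome may be shorter than the
resolution. Bins carry a *global* index (row order of the bin table), which is
how masks, weights and per-bin tracks are addressed throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["GenomeSpec", "read_chrom_sizes", "write_chrom_sizes"]


@dataclass(frozen=True)
class GenomeSpec:
    """A set of chromosomes with lengths, a bin size and optional arm splits.

    Parameters
    ----------
    chromosomes
        Sequence of ``(name, length_bp)`` pairs; order is preserved.
    bin_size
        Bin width in bp.
    arm_split
        Optional mapping ``chrom -> centromere position (bp)``; splits that
        chromosome into two arms for expected/P(s) computations. A position
        must lie strictly inside the chromosome.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    arm_split: Mapping[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(c), int(n)) for c, n in self.chromosomes))
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if self.arm_split is not None:
            sizes = dict(self.chromosomes)
            for name, pos in self.arm_split.items():
                if name not in sizes:
                    raise ValueError(f"arm_split names unknown chromosome {name!r}")
                if not 0 < pos < sizes[name]:
                    raise ValueError(f"arm split {pos} not strictly inside {name!r}")

    # -- bin bookkeeping ---------------------------------------------------

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def n_bins_of(self, chrom: str) -> int:
        return -(-self.sizes[chrom] // self.bin_size)

    @property
    def n_bins(self) -> int:
        return sum(self.n_bins_of(c) for c in self.chrom_names)

    def chrom_offsets(self) -> dict[str, int]:
        """Global index of the first bin of each chromosome."""
        out, acc = {}, 0
        for c in self.chrom_names:
            out[c] = acc
            acc += self.n_bins_of(c)
        return out

    def chrom_bounds(self) -> dict[str, tuple[int, int]]:
        """Half-open global-index range of each chromosome's bins."""
        off = self.chrom_offsets()
        return {c: (off[c], off[c] + self.n_bins_of(c)) for c in self.chrom_names}

    def bin_table(self) -> pd.DataFrame:
        rows = []
        for chrom, length in self.chromosomes:
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def with_bin_size(self, bin_size: int) -> "GenomeSpec":
        return GenomeSpec(self.chromosomes, bin_size, self.arm_split)

    def arms(self) -> list[tuple[str, int, int]]:
        """Arm intervals in bp; a chromosome without a split is one arm."""
        out = []
        for chrom, length in self.chromosomes:
            split = (self.arm_split or {}).get(chrom)
            if split is None:
                out.append((chrom, 0, length))
            else:
                out.append((chrom, 0, split))
                out.append((chrom, split, length))
        return out

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing bp position ``pos``."""
        if not 0 <= pos < self.sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return self.chrom_offsets()[chrom] + pos // self.bin_size


def read_chrom_sizes(path, bin_size: int) -> GenomeSpec:
    """Build a :class:`GenomeSpec` from a two-column ``chrom.sizes`` file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], dtype={"chrom": str})
    return GenomeSpec(tuple(zip(df["chrom"], df["size"].astype(int))), bin_size)


def write_chrom_sizes(genome: GenomeSpec, path) -> None:
    with open(path, "w") as fh:
        for chrom, size in genome.chromosomes:
            fh.write(f"{chrom}\t{size}\n")
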