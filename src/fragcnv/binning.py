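"""Genome discretization: fixed bin grids, fragment binning, aggregation.

Coordinates are 0-based half-open throughout.  Bins are ``[i*bin_size,
(i+1)*bin_size)``; the last bin of each chromosome may be short.  Only the
chromosomes named in the grid participate — by convention the autosomes.
"""
from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BASE_BIN = 5_000

_AUTOSOME_RE = re.compile(r"^(chr)?([0-9]{1,2})$")


def is_autosome(name: str) -> bool:
    m = _AUTOSOME_RE.match(name)
    return m is not None and 1 <= int(m.group(2)) <= 22


@dataclass(frozen=True)
class BinGrid:
    """A fixed partition of a set of chromosomes into equal-size bins.

    Parameters
    ----------
    chrom_order
        Ordered chromosome names (typically autosomes 1-22).
    chrom_lengths
        Chromosome lengths in bp, parallel to ``chrom_order``.
    bin_size
        Bin width in bp; must be a positive multiple of 5 kb.
    """

    chrom_order: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int

    def __post_init__(self) -> None:
        if len(self.chrom_order) != len(self.chrom_lengths):
            raise ValueError("chrom_order and chrom_lengths length mismatch")
        if len(self.chrom_order) != len(set(self.chrom_order)):
            raise ValueError("duplicate chromosome names in grid")
        if self.bin_size <= 0 or self.bin_size % BASE_BIN != 0:
            raise ValueError(
                f"bin_size must be a positive multiple of {BASE_BIN}, "
                f"got {self.bin_size}"
            )
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    # -- derived layout -------------------------------------------------

    @cached_property
    def bins_per_chrom(self) -> np.ndarray:
        lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        return -(-lengths // self.bin_size)  # ceil division

    @cached_property
    def chrom_offsets(self) -> np.ndarray:
        """Index of the first bin of each chromosome."""
        return np.concatenate([[0], np.cumsum(self.bins_per_chrom)])[:-1]

    @cached_property
    def n_bins(self) -> int:
        return int(self.bins_per_chrom.sum())

    @cached_property
    def bin_chrom(self) -> np.ndarray:
        """Per-bin chromosome code (index into chrom_order)."""
        return np.repeat(np.arange(len(self.chrom_order)), self.bins_per_chrom)

    @cached_property
    def bin_start(self) -> np.ndarray:
        local = np.arange(self.n_bins) - self.chrom_offsets[self.bin_chrom]
        return local * self.bin_size

    @cached_property
    def bin_end(self) -> np.ndarray:
        lengths = np.asarray(self.chrom_lengths, dtype=np.int64)
        return np.minimum(self.bin_start + self.bin_size, lengths[self.bin_chrom])

    @cached_property
    def short_bin(self) -> np.ndarray:
        """Flags terminal bins narrower than bin_size (kept, but flagged)."""
        return (self.bin_end - self.bin_start) < self.bin_size

    @cached_property
    def chrom_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chrom_order)}

    @cached_property
    def grid_hash(self) -> str:
        h = hashlib.md5(
            repr((self.chrom_order, self.chrom_lengths, self.bin_size)).encode()
        )
        return h.hexdigest()[:12]

    # -- queries --------------------------------------------------------

    def bin_index(self, chrom: str, pos: int) -> int:
        ci = self.chrom_index[chrom]
        if not 0 <= pos < self.chrom_lengths[ci]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self.chrom_offsets[ci] + pos // self.bin_size)

    def with_bin_size(self, bin_size: int) -> "BinGrid":
        return replace(self, bin_size=bin_size)

    @classmethod
    def from_chrom_sizes(
        cls,
        path: str | Path,
        bin_size: int,
        autosomes_only: bool = True,
    ) -> "BinGrid":
        """Build a grid from a 2-column chrom.sizes file or a FASTA .fai."""
        names: list[str] = []
        lengths: list[int] = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed chrom sizes line: {line!r}")
            name, length = parts[0], int(parts[1])
            if autosomes_only and not is_autosome(name):
                continue
            names.append(name)
            lengths.append(length)
        if not names:
            raise ValueError(f"no usable chromosomes in {path}")
        return cls(tuple(names), tuple(lengths), bin_size)


@dataclass
class BinnedSample:
    """Per-bin read counts plus fragment-size sums on a fixed grid.

    ``fs_sum``/``fs_n`` accumulate fragment sizes per bin; the per-bin mean
    fragment size is defined only where ``fs_n > 0``.  ``fs_mask`` marks bins
    whose fragment-size signal is considered usable (True = usable).
    """

    sample_id: str
    grid: BinGrid
    counts: np.ndarray
    fs_sum: np.ndarray
    fs_n: np.ndarray
    fs_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.grid.n_bins
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.fs_sum = np.asarray(self.fs_sum, dtype=np.float64)
        self.fs_n = np.asarray(self.fs_n, dtype=np.int64)
        if self.fs_mask is None:
            self.fs_mask = np.ones(n, dtype=bool)
        self.fs_mask = np.asarray(self.fs_mask, dtype=bool)
        for name in ("counts", "fs_sum", "fs_n", "fs_mask"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} has wrong length for grid")
        if np.any(self.fs_sum[self.fs_n == 0] != 0):
            raise ValueError("fs_sum must be 0 where fs_n is 0")

    @property
    def fs_mean(self) -> np.ndarray:
        """Per-bin mean fragment size; NaN where fs_n == 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.fs_n > 0, self.fs_sum / self.fs_n, np.nan)

    def copy(self) -> "BinnedSample":
        return BinnedSample(
            self.sample_id,
            self.grid,
            self.counts.copy(),
            self.fs_sum.copy(),
            self.fs_n.copy(),
            self.fs_mask.copy(),
        )

    # -- serialization (runtime artifacts; npz with embedded grid) ------

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            format_version=1,
            sample_id=self.sample_id,
            grid_hash=self.grid.grid_hash,
            chrom_order=np.asarray(self.grid.chrom_order),
            chrom_lengths=np.asarray(self.grid.chrom_lengths, dtype=np.int64),
            bin_size=self.grid.bin_size,
            counts=self.counts,
            fs_sum=self.fs_sum,
            fs_n=self.fs_n,
            fs_mask=self.fs_mask,
        )

    @classmethod
    def load(cls, path: str | Path) -> "BinnedSample":
        with np.load(path, allow_pickle=False) as z:
            grid = BinGrid(
                tuple(str(c) for c in z["chrom_order"]),
                tuple(int(l) for l in z["chrom_lengths"]),
                int(z["bin_size"]),
            )
            if str(z["grid_hash"]) != grid.grid_hash:
                raise ValueError(f"grid hash mismatch in {path}")
            return cls(
                str(z["sample_id"]),
                grid,
                z["counts"],
                z["fs_sum"],
                z["fs_n"],
                z["fs_mask"],
            )


def bin_fragments(
    fragments: pd.DataFrame,
    grid: BinGrid,
    sample_id: str = "sample",
) -> BinnedSample:
    """Assign fragments (by midpoint) to grid bins.

    Each fragment increments exactly one bin's count and contributes its size
    to that bin's ``fs_sum``/``fs_n``.  Fragments on chromosomes outside the
    grid are dropped (their number is recorded on the returned sample as
    ``n_off_grid``).  A midpoint beyond the chromosome length is an error.
    """
    counts = np.zeros(grid.n_bins, dtype=np.int64)
    fs_sum = np.zeros(grid.n_bins, dtype=np.float64)
    off_grid = 0
    for chrom, sub in fragments.groupby("chrom", sort=False, observed=True):
        ci = grid.chrom_index.get(str(chrom))
        if ci is None:
            off_grid += len(sub)
            continue
        mid = sub["midpoint"].to_numpy(dtype=np.int64)
        if mid.size and (mid.min() < 0 or mid.max() >= grid.chrom_lengths[ci]):
            bad = mid[(mid < 0) | (mid >= grid.chrom_lengths[ci])][0]
            raise ValueError(
                f"midpoint {bad} outside chromosome {chrom} "
                f"(length {grid.chrom_lengths[ci]}): corrupt input"
            )
        idx = grid.chrom_offsets[ci] + mid // grid.bin_size
        nb = grid.bins_per_chrom[ci]
        counts[grid.chrom_offsets[ci] : grid.chrom_offsets[ci] + nb] += np.bincount(
            idx - grid.chrom_offsets[ci], minlength=nb
        )
        fs_sum[grid.chrom_offsets[ci] : grid.chrom_offsets[ci] + nb] += np.bincount(
            idx - grid.chrom_offsets[ci],
            weights=sub["size"].to_numpy(dtype=np.float64),
            minlength=nb,
        )
    out = BinnedSample(sample_id, grid, counts, fs_sum, counts.copy())
    out.n_off_grid = off_grid  # type: ignore[attr-defined]
    return out


def aggregate(binned: BinnedSample, target_bin_size: int) -> BinnedSample:
    """Sum counts/fs_sum/fs_n into a coarser grid.

    ``target_bin_size`` must be a multiple of the current bin size; totals are
    conserved per chromosome.  Aggregating to the current size is the
    identity (a copy).
    """
    cur = binned.grid.bin_size
    if target_bin_size % cur != 0:
        raise ValueError(
            f"target bin size {target_bin_size} is not a multiple of {cur}"
        )
    if target_bin_size == cur:
        return binned.copy()
    factor = target_bin_size // cur
    new_grid = binned.grid.with_bin_size(target_bin_size)
    # map each old bin to its new bin index
    old, new = binned.grid, new_grid
    local = np.arange(old.n_bins) - old.chrom_offsets[old.bin_chrom]
    new_idx = new.chrom_offsets[old.bin_chrom] + local // factor
    counts = np.bincount(new_idx, weights=binned.counts, minlength=new.n_bins)
    fs_sum = np.bincount(new_idx, weights=binned.fs_sum, minlength=new.n_bins)
    fs_n = np.bincount(new_idx, weights=binned.fs_n, minlength=new.n_bins)
    return BinnedSample(
        binned.sample_id,
        new_grid,
        counts.astype(np.int64),
        fs_sum,
        fs_n.astype(np.int64),
    )


def fs_region_filter(
    binned: BinnedSample,
    min_frags: int = 10,
    max_cov_z: float = 3.0,
) -> BinnedSample:
    """Per-sample reliability filter on the fragment-size signal.

    Clears ``fs_mask`` where a bin holds fewer than ``min_frags`` fragments,
    or where its normalized read count exceeds the sample's cross-bin mean by
    more than ``max_cov_z`` standard deviations.  Counts are untouched.  The
    bounds are configuration defaults, not published values.
    """
    out = binned.copy()
    total = binned.counts.sum()
    if total > 0:
        norm = binned.counts / total
        sd = norm.std()
        if sd > 0:
            z = (norm - norm.mean()) / sd
            out.fs_mask &= z <= max_cov_z
    out.fs_mask &= binned.fs_n >= min_frags
    return out
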