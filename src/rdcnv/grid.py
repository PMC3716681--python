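"""The genome bin lattice.

All depth and copy-number tracks in this package live on a fixed grid of
non-overlapping, contiguous bins (default 1 kb) laid across an ordered set of
chromosomes. Bins are indexed globally, chromosome by chromosome, and all
coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidConfigError

__all__ = ["BinGrid"]


@dataclass
class BinGrid:
    """A genome-wide lattice of fixed-width bins with per-bin GC and mask tracks.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_in_bases)`` pairs. In simulated genomes every
        length is an exact multiple of ``bin_size``; when ingesting real data
        a trailing partial bin is dropped by the reader.
    bin_size
        Bin width in bases (default 1000).
    gc
        Per-bin GC fraction in [0, 1], concatenated over chromosomes.
    masked_frac
        Per-bin repeat-masked fraction in [0, 1].
    is_x
        Per-chromosome flag marking the X chromosome.
    par_regions
        Pseudo-autosomal intervals on X (base coordinates, half-open); PAR
        bins follow the autosomal copy-number rule in males.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    gc: np.ndarray
    masked_frac: np.ndarray
    is_x: tuple[bool, ...]
    par_regions: tuple[tuple[int, int], ...] = ()

    _offsets: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        self.chromosomes = tuple((str(n), int(l)) for n, l in self.chromosomes)
        self.is_x = tuple(bool(b) for b in self.is_x)
        if len(self.is_x) != len(self.chromosomes):
            raise InvalidConfigError("is_x must have one flag per chromosome")
        if self.bin_size <= 0:
            raise InvalidConfigError("bin_size must be positive")
        self.gc = np.asarray(self.gc, dtype=float)
        self.masked_frac = np.asarray(self.masked_frac, dtype=float)
        offsets, start = {}, 0
        for name, length in self.chromosomes:
            nb = length // self.bin_size
            offsets[name] = (start, nb)
            start += nb
        self._offsets = offsets
        if self.gc.shape != (start,) or self.masked_frac.shape != (start,):
            raise InvalidConfigError(
                f"gc/masked_frac must have {start} entries (one per bin)"
            )
        for arr, label in ((self.gc, "gc"), (self.masked_frac, "masked_frac")):
            if np.any((arr < 0) | (arr > 1)):
                raise InvalidConfigError(f"{label} values must lie in [0, 1]")

    # ------------------------------------------------------------------ sizes
    @property
    def n_bins(self) -> int:
        return int(self.gc.shape[0])

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def genome_size(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def chrom_length(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def n_bins_chrom(self, chrom: str) -> int:
        return self._offsets[chrom][1]

    # --------------------------------------------------------------- indexing
    def chrom_slice(self, chrom: str) -> slice:
        start, nb = self._offsets[chrom]
        return slice(start, start + nb)

    def bin_range(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Global index range of bins overlapping ``[start, end)`` on chrom."""
        off, nb = self._offsets[chrom]
        lo = max(0, start // self.bin_size)
        hi = min(nb, -(-end // self.bin_size))  # ceil division
        if hi <= lo:
            return off, off
        return off + lo, off + hi

    def bin_coords(self, index: int) -> tuple[str, int, int]:
        """``(chrom, start, end)`` of the bin at a global index."""
        for name, _ in self.chromosomes:
            off, nb = self._offsets[name]
            if off <= index < off + nb:
                local = index - off
                return name, local * self.bin_size, (local + 1) * self.bin_size
        raise IndexError(index)

    def chrom_of_bins(self) -> np.ndarray:
        """Per-bin chromosome index (into ``chromosomes``)."""
        out = np.empty(self.n_bins, dtype=np.int64)
        for i, (name, _) in enumerate(self.chromosomes):
            out[self.chrom_slice(name)] = i
        return out

    def bin_starts(self) -> np.ndarray:
        """Per-bin start coordinate on its own chromosome."""
        out = np.empty(self.n_bins, dtype=np.int64)
        for name, _ in self.chromosomes:
            sl = self.chrom_slice(name)
            out[sl] = np.arange(sl.stop - sl.start, dtype=np.int64) * self.bin_size
        return out

    # ------------------------------------------------------------------- sex
    @property
    def x_name(self) -> str | None:
        for (name, _), isx in zip(self.chromosomes, self.is_x):
            if isx:
                return name
        return None

    def x_bin_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_bins, dtype=bool)
        for (name, _), isx in zip(self.chromosomes, self.is_x):
            if isx:
                mask[self.chrom_slice(name)] = True
        return mask

    def par_bin_mask(self) -> np.ndarray:
        """Bins on X overlapping a pseudo-autosomal region."""
        mask = np.zeros(self.n_bins, dtype=bool)
        x = self.x_name
        if x is None:
            return mask
        for start, end in self.par_regions:
            lo, hi = self.bin_range(x, start, end)
            mask[lo:hi] = True
        return mask

    def regions_bin_mask(self, regions) -> np.ndarray:
        """Bins overlapping any interval of a (chrom, start, end) table."""
        mask = np.zeros(self.n_bins, dtype=bool)
        for chrom, start, end in zip(regions["chrom"], regions["start"], regions["end"]):
            if chrom not in self._offsets:
                continue
            lo, hi = self.bin_range(chrom, int(start), int(end))
            mask[lo:hi] = True
        return mask
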