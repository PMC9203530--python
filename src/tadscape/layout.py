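"""Genome layout: chromosome names/lengths and the bin size shared by all tracks.

Every binned object in the package (contact matrices, feature tracks,
boundary intervals, expression bins) is indexed against a single
:class:`GenomeLayout`.  Coordinates are 0-based, half-open; the bin holding
position ``p`` is ``p // bin_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes plus the bin size defining all binned coordinates.

    Parameters
    ----------
    chrom_names:
        Ordered chromosome identifiers.
    chrom_lengths:
        Length in bp per chromosome, same order as ``chrom_names``.
    bin_size:
        Bin width in bp (e.g. 40_000 for a 40-kb analysis).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]
    bin_size: int
    _index: dict = field(init=False, repr=False, compare=False)

    def __init__(self, chrom_names, chrom_lengths, bin_size):
        chrom_names = tuple(str(c) for c in chrom_names)
        chrom_lengths = tuple(int(l) for l in chrom_lengths)
        if len(chrom_names) != len(chrom_lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(chrom_names)) != len(chrom_names):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        object.__setattr__(self, "chrom_names", chrom_names)
        object.__setattr__(self, "chrom_lengths", chrom_lengths)
        object.__setattr__(self, "bin_size", int(bin_size))
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(chrom_names)})

    def length(self, chrom: str) -> int:
        return self.chrom_lengths[self._index[chrom]]

    def n_bins(self, chrom: str) -> int:
        """Number of bins on ``chrom`` = ceil(length / bin_size)."""
        l = self.length(chrom)
        return -(-l // self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_lengths)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._index

    def bin_of(self, chrom: str, pos: int) -> int:
        """Bin index on its chromosome for 0-based position ``pos``."""
        if not 0 <= pos < self.length(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.bin_size

    def bin_start(self, bin_index: int) -> int:
        return bin_index * self.bin_size

    def bin_starts(self, chrom: str):
        import numpy as np

        return np.arange(self.n_bins(chrom)) * self.bin_size
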