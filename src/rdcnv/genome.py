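"""Genome layout and ground-truth CNV containers.

All coordinates in this package are 0-based half-open; conversion to the
1-based inclusive conventions of GTF and the caller's text dialect happens
only in :mod:`rdcnv.io`.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class GenomeLayout:
    """An ordered set of named chromosomes with lengths in base pairs."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(f"unknown chromosome {chrom!r}")

    def __contains__(self, chrom: str) -> bool:
        return any(name == chrom for name, _ in self.chromosomes)


@dataclass(frozen=True, order=True)
class TruthCNV:
    """A ground-truth implanted copy-number event (diploid baseline is 2).

    ``copy_number`` is the absolute integer copy number of the region:
    0 or 1 for deletions, 3+ for duplications.
    """

    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.copy_number == 2:
            raise ValueError("copy_number 2 is the diploid baseline, not a CNV")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def is_deletion(self) -> bool:
        return self.copy_number < 2
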