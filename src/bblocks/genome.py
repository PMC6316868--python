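"""Reference genome geometry: chromosome names and lengths.

All coordinates in this package are 0-based, half-open. Inputs that use
1-based positions (samtools-depth TSV) are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class GenomeValidationError(ValueError):
    """Raised when a genome index or a record violates genome constraints."""


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered chromosome-name -> length (bp) table.

    Chromosome order is preserved from the input file; names must be unique
    and lengths positive.
    """

    chroms: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chroms:
            raise GenomeValidationError("genome index has no chromosomes")
        for name, length in self.chroms.items():
            if not isinstance(length, int) or length < 1:
                raise GenomeValidationError(
                    f"chromosome {name!r} has invalid length {length!r}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.chroms)

    @property
    def total_length(self) -> int:
        return sum(self.chroms.values())

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __len__(self) -> int:
        return len(self.chroms)

    def length_of(self, name: str) -> int:
        try:
            return self.chroms[name]
        except KeyError:
            raise GenomeValidationError(f"unknown chromosome {name!r}") from None

    def check_interval(self, chrom: str, start: int, end: int) -> None:
        """Validate a 0-based half-open interval against the index."""
        length = self.length_of(chrom)
        if not (0 <= start < end <= length):
            raise GenomeValidationError(
                f"interval {chrom}:{start}-{end} outside chromosome bounds "
                f"(length {length})"
            )
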