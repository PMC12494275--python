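"""Genome models: chromosome lengths and centromere intervals.

All coordinates are 0-based half-open. Segment inputs declared 1-based
inclusive are converted on read (see :mod:`hgsoctx.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigError


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths (bp) and centromere intervals (0-based half-open)."""

    chrom_lengths: dict[str, int]
    centromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ConfigError(f"chromosome {chrom} has non-positive length {length}")
            cen = self.centromeres.get(chrom)
            if cen is not None:
                lo, hi = cen
                if not (0 <= lo < hi <= length):
                    raise ConfigError(
                        f"centromere {cen} outside chromosome {chrom} [0, {length})"
                    )

    def length(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[chrom]
        except KeyError:
            raise ConfigError(f"chromosome {chrom!r} not in genome model") from None

    def centromere(self, chrom: str) -> tuple[int, int]:
        try:
            return self.centromeres[chrom]
        except KeyError:
            raise ConfigError(f"no centromere declared for chromosome {chrom!r}") from None


MB = 1_000_000


def reduced_genome(n_chroms: int = 5, chrom_mb: int = 100) -> GenomeModel:
    """Desk-scale genome: ``n_chroms`` chromosomes of ``chrom_mb`` Mb each,
    centromere occupying the central 5% of every chromosome."""
    length = chrom_mb * MB
    half_cen = length // 40
    return GenomeModel(
        chrom_lengths={f"chr{i + 1}": length for i in range(n_chroms)},
        centromeres={
            f"chr{i + 1}": (length // 2 - half_cen, length // 2 + half_cen)
            for i in range(n_chroms)
        },
    )
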