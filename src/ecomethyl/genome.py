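"""Genome geometry: chromosome sizes and pericentromere intervals."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names/lengths plus optional pericentromere intervals.

    Coordinates are 0-based half-open throughout the package.
    """

    chrom_sizes: dict[str, int]
    pericentromeres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("genome must have at least one chromosome")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {size}")
        for chrom, (start, end) in self.pericentromeres.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"pericentromere on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= self.chrom_sizes[chrom]):
                raise ValueError(
                    f"pericentromere [{start}, {end}) outside chromosome {chrom!r}"
                )

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    @property
    def total_bp(self) -> int:
        return sum(self.chrom_sizes.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes

    @classmethod
    def default_toy(cls) -> "GenomeSpec":
        """Desk-scale default: 2 x 500 kb with 50 kb central pericentromeres."""
        return cls(
            chrom_sizes={"chr1": 500_000, "chr2": 500_000},
            pericentromeres={"chr1": (225_000, 275_000), "chr2": (225_000, 275_000)},
        )

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeSpec":
        peri = {k: (int(v[0]), int(v[1])) for k, v in d.get("pericentromeres", {}).items()}
        return cls(
            chrom_sizes={k: int(v) for k, v in d["chromosomes"].items()},
            pericentromeres=peri,
        )

    def to_dict(self) -> dict:
        return {
            "chromosomes": dict(self.chrom_sizes),
            "pericentromeres": {k: list(v) for k, v in self.pericentromeres.items()},
        }
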