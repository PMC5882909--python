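"""Shared domain types: gene models and protein records."""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


class ValidationError(ValueError):
    """Raised when an input record violates a structural invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence (20-letter alphabet, optional X)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - AA_ALPHABET - {"X"}
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: illegal symbols {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    """One gene's location and exon structure (1-based, inclusive)."""

    id: str
    chromosome: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.id!r}: strand must be '+' or '-'")
        if self.start > self.end:
            raise ValidationError(f"gene {self.id!r}: start > end")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a > b:
                raise ValidationError(f"gene {self.id!r}: exon start > end")
            if a < self.start or b > self.end:
                raise ValidationError(
                    f"gene {self.id!r}: exon ({a},{b}) outside gene bounds"
                )
            if prev_end is not None and a <= prev_end:
                raise ValidationError(f"gene {self.id!r}: overlapping exons")
            prev_end = b

    @property
    def intron_count(self) -> int:
        return max(len(self.exons) - 1, 0)
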