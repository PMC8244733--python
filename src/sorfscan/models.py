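"""Core domain types shared across the pipeline stages.

All internal coordinates are 0-based half-open. Transcript coordinates run
5'->3' along the spliced transcript; genomic coordinates follow the reference
strand. Emitted GTF is 1-based inclusive (see :mod:`sorfscan.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "SEVEN_CLASSES",
    "INFRAME_NESTED",
    "STOP_CODONS",
    "START_CODON",
    "SorfscanError",
    "ConfigurationError",
    "GeometryError",
    "UndefinedValueError",
    "InputValidationError",
    "TranscriptModel",
    "OrfRecord",
    "PeriodicityResult",
]

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: The seven positional ORF classes, in reporting order.
SEVEN_CLASSES = (
    "annotated",
    "uORF",
    "dORF",
    "Overlap_uORF",
    "Overlap_dORF",
    "Internal",
    "novel",
)

#: Same-frame ORFs nested inside the CDS with boundaries not both equal to the
#: CDS bounds; excluded from the seven-class output.
INFRAME_NESTED = "inframe_nested"


class SorfscanError(Exception):
    """Base class for package errors."""


class ConfigurationError(SorfscanError):
    """Invalid configuration."""


class GeometryError(ConfigurationError):
    """A planted ORF cannot fit the host transcript geometry."""


class UndefinedValueError(SorfscanError):
    """A quantity is undefined for the given inputs (e.g. zero library size)."""


class InputValidationError(SorfscanError):
    """An input file violates its schema."""


@dataclass(frozen=True)
class TranscriptModel:
    """A strand-resolved transcript: the coordinate frame for everything else.

    Parameters
    ----------
    exons
        Genomic intervals, 0-based half-open, ordered 5'->3' along the
        transcript (descending genomic start on the minus strand).
    sequence
        Spliced transcript sequence, 5'->3' (already reverse-complemented for
        minus-strand transcripts).
    cds
        Annotated CDS in transcript coordinates, including the stop codon;
        ``None`` marks a non-coding transcript.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    sequence: str
    cds: Optional[tuple[int, int]] = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ConfigurationError(f"bad strand {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        for s, e in exons:
            if not 0 <= s < e:
                raise ConfigurationError(f"bad exon interval ({s}, {e})")
        genomic_sorted = sorted(exons)
        for (_, e1), (s2, _) in zip(genomic_sorted, genomic_sorted[1:]):
            if s2 < e1:
                raise ConfigurationError(
                    f"overlapping exons on {self.transcript_id}"
                )
        expected = genomic_sorted if self.strand == "+" else genomic_sorted[::-1]
        if exons != tuple(expected):
            raise ConfigurationError(
                f"exons of {self.transcript_id} not ordered 5'->3'"
            )
        if self.sequence and len(self.sequence) != self.length:
            raise ConfigurationError(
                f"sequence length {len(self.sequence)} != exon span {self.length}"
                f" on {self.transcript_id}"
            )
        if self.cds is not None:
            cs, ce = self.cds
            if not (0 <= cs < ce <= self.length):
                raise ConfigurationError(f"CDS outside {self.transcript_id}")
            if (ce - cs) % 3:
                raise ConfigurationError(
                    f"CDS length not divisible by 3 on {self.transcript_id}"
                )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds is not None

    def to_genomic(self, start: int, end: int) -> list[tuple[int, int]]:
        """Project a transcript interval onto the genome.

        Returns genomic blocks (0-based half-open) in ascending genomic order.
        """
        if not 0 <= start <= end <= self.length:
            raise ValueError(f"interval [{start}, {end}) outside transcript")
        blocks: list[tuple[int, int]] = []
        offset = 0
        for gs, ge in self.exons:
            exon_len = ge - gs
            lo = max(start, offset)
            hi = min(end, offset + exon_len)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((gs + lo - offset, gs + hi - offset))
                else:
                    blocks.append((ge - (hi - offset), ge - (lo - offset)))
            offset += exon_len
        return sorted(blocks)


@dataclass(frozen=True)
class OrfRecord:
    """A candidate or called ORF in transcript coordinates.

    ``[start, end)`` spans the start codon through the stop codon inclusive,
    so the coding length excluding the stop is ``end - start - 3``.
    """

    orf_id: str
    transcript_id: str
    start: int
    end: int
    peptide: str
    orf_class: Optional[str] = None
    samples: tuple[str, ...] = ()
    min_adjusted_p: Optional[float] = None
    genomic_blocks: Optional[tuple[tuple[int, int], ...]] = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 or self.end - self.start < 6:
            raise ConfigurationError(
                f"ORF [{self.start}, {self.end}) is not a codon-multiple span"
            )

    @property
    def cds_len_nt(self) -> int:
        return self.end - self.start - 3

    @property
    def peptide_length(self) -> int:
        return len(self.peptide)

    @property
    def is_sorf(self) -> bool:
        """Small ORF: peptide of 2-100 aa (CDS 6-300 nt excluding the stop)."""
        return 2 <= self.peptide_length <= 100

    def with_class(self, label: str) -> "OrfRecord":
        return replace(self, orf_class=label)


@dataclass
class PeriodicityResult:
    """Outcome of the three-nucleotide periodicity test for one ORF/sample."""

    orf_id: str
    sample: str
    n_informative_codons: int
    statistic: float
    p_value: float
    adjusted_p: Optional[float] = None
    called: bool = False
    reason: Optional[str] = None
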