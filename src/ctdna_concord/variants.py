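"""Somatic variant records tracked from tumor to plasma.

Coordinates are 0-based, half-open throughout the package; conversion to
VCF's 1-based convention happens only at the file boundary (see
:mod:`ctdna_concord.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

SNV = "SNV"
MULTI_BASE_INDEL = "multi_base_indel"
SINGLE_BASE_INDEL = "single_base_indel"
VARIANT_TYPES = (SNV, MULTI_BASE_INDEL, SINGLE_BASE_INDEL)


@dataclass(frozen=True, order=True)
class Locus:
    """A genomic query position with its reference and alternate allele."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class TumorVariant:
    """One somatic mutation identified in a solid tumor.

    This is the query object: its mutational status is tracked in the
    matched plasma sample by ddPCR or NGS.
    """

    sample_id: str
    locus: Locus
    gene: str = ""
    protein_change: str = ""
    variant_type: str = SNV
    tumor_maf_pct: float = float("nan")

    def __post_init__(self) -> None:
        if self.variant_type not in VARIANT_TYPES:
            raise ValueError(f"unknown variant type {self.variant_type!r}")


def is_indel(variant_type: str) -> bool:
    return variant_type in (MULTI_BASE_INDEL, SINGLE_BASE_INDEL)
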