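"""Plasma variant detection from read families.

Four detection procedures, all operating in check-known-variants (CKV)
mode — the query locus and alternate allele come from the matched tumor
profile, never from de novo discovery:

``dnaseq_positional``
    Endogenous-UMI chemistry. Reads sharing alignment start and end are
    assumed to derive from one cfDNA molecule and grouped into a family;
    a variant is bona fide when at least two families of >=5 reads each
    have >95% (strictly) of their reads supporting it.
``tagseq_ckv``
    Tagged-UMI chemistry. Families (position + UMI) are collapsed to
    consensus reads; the variant is called when its consensus supporting
    read percentage (%SR) reaches 0.4% for SNVs or 0.2% for multi-base
    indels.
``generead``
    Tagged-UMI amplicon chemistry with a family-support gate: at least
    two families of >=3 reads whose consensus is the variant.
``amplicon``
    No UMIs. A binomial caller over raw reads: depth >=10, >=2 variant
    reads, Phred-scaled binomial-tail confidence >=50, and %SR >=0.3
    (SNV) / >=0.2 (multi-base indel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd
from scipy import stats

from .errors import InputError
from .variants import MULTI_BASE_INDEL, SINGLE_BASE_INDEL, SNV


@dataclass
class CallerThresholds:
    """Every tunable gate of the four procedures, with assay defaults."""

    dnaseq_min_family: int = 5
    dnaseq_min_families: int = 2
    dnaseq_consistency: float = 0.95  # strict >
    generead_min_family: int = 3
    generead_min_families: int = 2
    amplicon_min_depth: int = 10
    amplicon_min_var_reads: int = 2
    amplicon_min_confidence: float = 50.0
    snp_sr_pct: float = 0.3
    indel_sr_pct: float = 0.2
    ckv_snp_sr_pct: float = 0.4
    ckv_indel_sr_pct: float = 0.2
    # the %SR rules name multi-base indels explicitly; single-base indels
    # follow the indel threshold unless this flag reclassifies them
    single_base_indel_as_snv: bool = False

    def sr_threshold(self, variant_type: str, ckv: bool = False) -> float:
        treat_as_snv = variant_type == SNV or (
            variant_type == SINGLE_BASE_INDEL and self.single_base_indel_as_snv
        )
        if ckv:
            return self.ckv_snp_sr_pct if treat_as_snv else self.ckv_indel_sr_pct
        return self.snp_sr_pct if treat_as_snv else self.indel_sr_pct


DEFAULT_THRESHOLDS = CallerThresholds()


@dataclass
class ReadFamily:
    """Reads sharing one (positional or tagged) molecular identifier."""

    key: tuple
    size: int
    allele_counts: dict[str, int]
    consensus_allele: str | None  # None when no strict majority
    consistency: float  # fraction of reads matching the consensus

    @classmethod
    def from_counts(cls, key: tuple, counts: dict[str, int]) -> "ReadFamily":
        size = sum(counts.values())
        top = max(counts.values())
        winners = [a for a, c in counts.items() if c == top]
        consensus = winners[0] if len(winners) == 1 else None
        return cls(
            key=key,
            size=size,
            allele_counts=dict(counts),
            consensus_allele=consensus,
            consistency=top / size,
        )


@dataclass
class PlasmaCall:
    """Outcome of one detection procedure at one locus."""

    sample_id: str
    locus: str
    procedure: str
    depth: int = 0
    supporting: int = 0
    sr_pct: float = 0.0
    supporting_families: int = 0
    confidence: float = float("nan")
    detected: bool = False
    reason: str = ""


def _group(reads: pd.DataFrame, keys: list[str]) -> list[ReadFamily]:
    if len(reads) == 0:
        return []
    fams = []
    counts = reads.groupby(keys + ["allele"], sort=True).size()
    key_levels = list(range(len(keys)))
    for key, sub in counts.groupby(level=key_levels, sort=True):
        fams.append(ReadFamily.from_counts(key, sub.droplevel(key_levels).to_dict()))
    return fams


def group_positional_families(reads: pd.DataFrame) -> list[ReadFamily]:
    """Group reads into endogenous-UMI families keyed by (chrom, start, end).

    All reads must share a chromosome — families are built per locus in
    CKV mode, never across contigs.
    """
    if len(reads) == 0:
        return []
    chroms = reads["chrom"].unique()
    if len(chroms) > 1:
        raise InputError(f"reads span multiple chromosomes: {sorted(chroms)}")
    return _group(reads, ["chrom", "start", "end"])


def group_umi_families(reads: pd.DataFrame) -> list[ReadFamily]:
    """Group reads into tagged-UMI families keyed by (chrom, start, end, umi)."""
    if len(reads) == 0:
        return []
    missing = reads.index[reads["umi"].isna() | (reads["umi"] == ".") | (reads["umi"] == "")]
    if len(missing):
        raise InputError(f"read at index {missing[0]} has no UMI tag")
    return _group(reads, ["chrom", "start", "end", "umi"])


def _totals(families: list[ReadFamily], alt: str) -> tuple[int, int]:
    depth = sum(f.size for f in families)
    supporting = sum(f.allele_counts.get(alt, 0) for f in families)
    return depth, supporting


def call_dnaseq_positional(
    families: list[ReadFamily],
    alt: str = "alt",
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    sample_id: str = "",
    locus: str = "",
) -> PlasmaCall:
    """Two-families-of->=5 rule with a strict >95% within-family consistency.

    A family supports the variant when its size is at least
    ``dnaseq_min_family``, its consensus is the alternate allele, and
    strictly more than ``dnaseq_consistency`` of its reads carry it.
    The variant is detected when at least ``dnaseq_min_families``
    families qualify. Note a 19/20 family fails: 0.95 is not > 0.95.
    """
    depth, supporting = _totals(families, alt)
    call = PlasmaCall(
        sample_id=sample_id,
        locus=locus,
        procedure="dnaseq_positional",
        depth=depth,
        supporting=supporting,
        sr_pct=100.0 * supporting / depth if depth else 0.0,
    )
    if not families:
        call.reason = "no_families"
        return call
    n_support = sum(
        1
        for f in families
        if f.size >= thresholds.dnaseq_min_family
        and f.consensus_allele == alt
        and f.consistency > thresholds.dnaseq_consistency
    )
    call.supporting_families = n_support
    if n_support >= thresholds.dnaseq_min_families:
        call.detected = True
    else:
        call.reason = "insufficient_families"
    return call


@dataclass
class ConsensusResult:
    """Consensus reads collapsed from UMI families."""

    reads: pd.DataFrame  # columns: key fields + allele
    n_families: int
    n_below_min_size: int
    n_dropped_ties: int


def collapse_consensus(families: list[ReadFamily], min_size: int = 1) -> ConsensusResult:
    """One consensus read per family of size >= min_size.

    The consensus allele is the strict majority; tied families carry no
    evidence either way and are dropped (counted in ``n_dropped_ties``).
    """
    rows = []
    below = ties = 0
    for f in families:
        if f.size < min_size:
            below += 1
            continue
        if f.consensus_allele is None:
            ties += 1
            continue
        rows.append({"key": f.key, "size": f.size, "allele": f.consensus_allele})
    reads = pd.DataFrame(rows, columns=["key", "size", "allele"])
    return ConsensusResult(
        reads=reads, n_families=len(families), n_below_min_size=below, n_dropped_ties=ties
    )


def call_tagseq_ckv(
    consensus: ConsensusResult | pd.DataFrame,
    alt: str = "alt",
    variant_type: str = SNV,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    sample_id: str = "",
    locus: str = "",
) -> PlasmaCall:
    """Check-known-variants call on consensus reads.

    Detected when the consensus %SR meets the lowered CKV thresholds:
    0.4% for SNVs, 0.2% for multi-base indels.
    """
    reads = consensus.reads if isinstance(consensus, ConsensusResult) else consensus
    depth = len(reads)
    supporting = int((reads["allele"] == alt).sum()) if depth else 0
    call = PlasmaCall(
        sample_id=sample_id,
        locus=locus,
        procedure="tagseq_ckv",
        depth=depth,
        supporting=supporting,
        sr_pct=100.0 * supporting / depth if depth else 0.0,
        supporting_families=supporting,
    )
    if depth == 0:
        call.reason = "no_depth"
        return call
    thr = thresholds.sr_threshold(variant_type, ckv=True)
    if call.sr_pct >= thr:
        call.detected = True
    else:
        call.reason = "sr_below_threshold"
    return call


def call_generead(
    families: list[ReadFamily],
    alt: str = "alt",
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    sample_id: str = "",
    locus: str = "",
) -> PlasmaCall:
    """Family-support gate: >=2 families of >=3 reads with alt consensus."""
    depth, supporting = _totals(families, alt)
    call = PlasmaCall(
        sample_id=sample_id,
        locus=locus,
        procedure="generead",
        depth=depth,
        supporting=supporting,
        sr_pct=100.0 * supporting / depth if depth else 0.0,
    )
    if not families:
        call.reason = "no_families"
        return call
    n_support = sum(
        1
        for f in families
        if f.size >= thresholds.generead_min_family and f.consensus_allele == alt
    )
    call.supporting_families = n_support
    if n_support >= thresholds.generead_min_families:
        call.detected = True
    else:
        call.reason = "insufficient_families"
    return call


def binomial_confidence(n_alt: int, depth: int, error_rate_null: float) -> float:
    """Phred-scaled upper-tail binomial p-value.

    ``-10 * log10 P(X >= n_alt)`` for X ~ Binomial(depth, error_rate_null):
    how surprising the observed variant-read count is under sequencing
    error alone. A score of 50 corresponds to p = 1e-5.
    """
    if n_alt <= 0:
        return 0.0
    p = stats.binom.sf(n_alt - 1, depth, error_rate_null)
    if p <= 0.0:
        return math.inf
    return -10.0 * math.log10(p)


def call_amplicon(
    reads: pd.DataFrame,
    alt: str = "alt",
    variant_type: str = SNV,
    error_rate_null: float = 0.001,
    thresholds: CallerThresholds = DEFAULT_THRESHOLDS,
    sample_id: str = "",
    locus: str = "",
) -> PlasmaCall:
    """Binomial caller over raw amplicon reads (no family structure).

    Gates, in order of evaluation: depth >= 10, variant reads >= 2,
    confidence >= 50 (see :func:`binomial_confidence`), and %SR >= 0.3
    for SNVs / >= 0.2 for multi-base indels. The first failing gate is
    recorded in ``reason``.
    """
    depth = len(reads)
    supporting = int((reads["allele"] == alt).sum()) if depth else 0
    call = PlasmaCall(
        sample_id=sample_id,
        locus=locus,
        procedure="amplicon",
        depth=depth,
        supporting=supporting,
        sr_pct=100.0 * supporting / depth if depth else 0.0,
        confidence=binomial_confidence(supporting, depth, error_rate_null),
    )
    if depth < thresholds.amplicon_min_depth:
        call.reason = "insufficient_depth"
    elif supporting < thresholds.amplicon_min_var_reads:
        call.reason = "insufficient_var_reads"
    elif call.sr_pct < thresholds.sr_threshold(variant_type):
        call.reason = "sr_below_threshold"
    elif call.confidence < thresholds.amplicon_min_confidence:
        call.reason = "low_confidence"
    else:
        call.detected = True
    return call
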